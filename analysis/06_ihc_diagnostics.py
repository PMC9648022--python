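"""Diagnostic evaluation of the IHC markers against the gold-standard stage.

On the simulated section cohort: per-marker confusion tables for the
high-grade-lesion detection task, sensitivity/specificity/PPV/NPV with exact
95% CIs, binary-test AUC, pairwise exact McNemar comparisons and Cohen's
kappa agreement, and serial/parallel combination of the best marker pair.
"""

import argparse
from pathlib import Path

import pandas as pd

from cervtrans import ihc
from cervtrans.io import read_marker_table


def metrics_row(calls, truth, label):
    ct = ihc.ConfusionTable.from_calls(calls, truth)
    m = ihc.diagnostic_metrics(ct)
    fmt = lambda e: f"{ihc.round_half_up(100 * e.value)} ({ihc.round_half_up(100 * e.ci_low)}-{ihc.round_half_up(100 * e.ci_high)})"
    return {
        "marker": label, "TP": ct.tp, "FN": ct.fn, "TN": ct.tn, "FP": ct.fp,
        "sensitivity_pct": fmt(m.sensitivity), "specificity_pct": fmt(m.specificity),
        "ppv_pct": fmt(m.ppv), "npv_pct": fmt(m.npv),
        "auc": f"{ihc.round_half_up(m.auc.value, 2)} ({ihc.round_half_up(m.auc.ci_low, 2)}-{ihc.round_half_up(m.auc.ci_high, 2)})",
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/ihc"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    wide = read_marker_table(args.in_dir / "ihc.csv").calls_wide()
    truth = (wide["gold_stage"] >= 2).astype(int)  # detect HSIL
    markers = [c for c in wide.columns if c not in ("gold_label", "gold_stage")]

    rows = [metrics_row(wide[m], truth, m) for m in markers]
    for a, b, mode in [("TOP2A", "RFC4", "parallel"), ("TOP2A", "RFC4", "serial")]:
        if a in markers and b in markers:
            combo = ihc.combine_markers(wide[a], wide[b], mode)
            rows.append(metrics_row(combo, truth, f"{a}+{b} ({mode})"))
    table = pd.DataFrame(rows)
    table.to_csv(args.out_dir / "diagnostic_metrics.tsv", sep="\t", index=False)
    print(table[["marker", "sensitivity_pct", "specificity_pct", "auc"]].to_string(index=False))

    pairs = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            kap = ihc.cohens_kappa(wide[a], wide[b])
            pairs.append(
                {"marker_a": a, "marker_b": b,
                 "mcnemar_p": ihc.mcnemar_from_calls(wide[a], wide[b]),
                 "kappa": kap.kappa, "agreement_pct": 100 * kap.po}
            )
    pd.DataFrame(pairs).to_csv(args.out_dir / "paired_comparisons.tsv", sep="\t", index=False)
    print(f"wrote {len(pairs)} paired-marker comparisons")


if __name__ == "__main__":
    main()
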