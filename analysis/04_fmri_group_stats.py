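#!/usr/bin/env python
"""Group statistics for the imaging arms.

Per experiment: one-way repeated-measures ANOVA over the four Chroma
conditions (on the un-normalized peaks) with Tukey HSD post-hoc tests;
then the main-vs-control magnitude comparison of the condition-averaged
responses (Welch t).
"""

import argparse
from pathlib import Path

import pandas as pd

from chromasupp.group_stats import compare_means, rm_anova_oneway, tukey_hsd


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/fmri"))
    args = parser.parse_args()

    magnitudes = {}
    for experiment in ("main", "control"):
        out = args.out / experiment
        peaks = pd.read_csv(out / "peaks.csv")
        values = peaks.rename(columns={"peak": "value"})[
            ["subject", "condition", "value"]]
        anova = rm_anova_oneway(values)
        anova.to_frame().to_csv(out / "peaks_anova.csv", index=False)
        comps = tukey_hsd(values, anova)
        pd.DataFrame([
            {"condition_a": c.pair[0], "condition_b": c.pair[1],
             "mean_difference": c.mean_difference, "q": c.q,
             "p_adjusted": c.p_adjusted} for c in comps
        ]).to_csv(out / "peaks_tukey.csv", index=False)
        stars = [f"{c.pair[0]} vs {c.pair[1]} p={c.p_adjusted:.3f}"
                 for c in comps if c.p_adjusted < 0.05]
        print(f"{experiment}: F({anova.df_cond},{anova.df_resid}) = "
              f"{anova.f_value:.3f}, p = {anova.p_value:.4f}; "
              f"significant pairs: {', '.join(stars) or 'none'}")
        magnitudes[experiment] = values.groupby("subject")["value"].mean()

    comp = compare_means(magnitudes["main"], magnitudes["control"],
                         mode="welch")
    print(f"main vs control magnitude: {magnitudes['main'].mean():.2f} vs "
          f"{magnitudes['control'].mean():.2f} % signal change, "
          f"Welch t = {comp.t:.2f}, p = {comp.p:.4f}")
    pd.DataFrame([{"t": comp.t, "df": comp.df, "p": comp.p,
                   "mode": comp.mode}]).to_csv(
        args.out / "main_vs_control_t.csv", index=False)


if __name__ == "__main__":
    main()
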