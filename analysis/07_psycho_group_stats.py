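#!/usr/bin/env python
"""Group statistics for the psychophysical arm.

Repeated-measures ANOVA on the fitted sigma values of the retained
observers, with Tukey HSD post-hoc pairs.  The question: is luminance
contrast discrimination selectively worse (larger sigma) when the weakly
saturated /2 patches flank the grating?
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chromasupp.group_stats import rm_anova_oneway, tukey_hsd
from chromasupp.hrf import CONDITIONS


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/psycho"))
    args = parser.parse_args()

    sigmas = pd.read_csv(args.out / "sigmas.csv")
    retained = json.loads((args.out / "exclusion.json").read_text())["retained"]
    values = sigmas[sigmas["subject"].isin(retained)].rename(
        columns={"chroma": "condition", "sigma": "value"})[
        ["subject", "condition", "value"]]

    anova = rm_anova_oneway(values)
    anova.to_frame().to_csv(args.out / "sigma_anova.csv", index=False)
    comps = tukey_hsd(values, anova)
    pd.DataFrame([
        {"condition_a": c.pair[0], "condition_b": c.pair[1],
         "mean_difference": c.mean_difference, "q": c.q,
         "p_adjusted": c.p_adjusted} for c in comps
    ]).to_csv(args.out / "sigma_tukey.csv", index=False)

    means = values.groupby("condition")["value"].mean()
    print("mean sigma: "
          + ", ".join(f"{c} {means[c]:.4f}" for c in CONDITIONS))
    print(f"ANOVA F({anova.df_cond},{anova.df_resid}) = {anova.f_value:.3f}, "
          f"p = {anova.p_value:.4f}")
    for c in comps:
        flag = " *" if c.p_adjusted < 0.05 else ""
        print(f"  {c.pair[0]} vs {c.pair[1]}: diff {c.mean_difference:+.4f}, "
              f"p = {c.p_adjusted:.4f}{flag}")


if __name__ == "__main__":
    main()
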