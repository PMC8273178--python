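#!/usr/bin/env python
"""Fit psychometric functions and apply the observer-exclusion rule.

Per (observer, Chroma condition): discard the first two sessions, pool
response rates over the rest, fit the cumulative Gaussian by maximum
likelihood, and report (mu, sigma).  Observers whose mean sigma exceeds
three times the cohort median are excluded before group statistics.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chromasupp import io
from chromasupp.psychometrics import (
    aggregate_rates,
    exclude_subjects,
    fit_psychometric,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--method", choices=["ml", "ls"], default="ml")
    parser.add_argument("--out", type=Path, default=Path("results/psycho"))
    args = parser.parse_args()

    trials = io.read_trials(args.out / "trials.csv")
    rows = []
    for subject, sub in trials.groupby("subject"):
        rates = aggregate_rates(sub)
        for chroma, table in rates.groupby("chroma"):
            fit = fit_psychometric(table, method=args.method)
            rows.append({"subject": subject, "chroma": chroma, "mu": fit.mu,
                         "sigma": fit.sigma, "method": fit.method,
                         "n_trials": fit.n_trials,
                         "flags": ";".join(fit.flags)})
    sigmas = pd.DataFrame(rows)
    sigmas.to_csv(args.out / "sigmas.csv", index=False)

    mean_sigma = sigmas.groupby("subject")["sigma"].mean()
    exclusion = exclude_subjects(mean_sigma.to_dict())
    (args.out / "exclusion.json").write_text(json.dumps({
        "threshold": exclusion.threshold,
        "retained": exclusion.retained,
        "excluded": exclusion.excluded,
    }, indent=1))
    kept = mean_sigma[exclusion.retained]
    print(f"mean sigma per observer: {kept.min():.3f}-{kept.max():.3f}; "
          f"excluded: "
          + (", ".join(f"{s} ({mean_sigma[s]:.3f})"
                       for s in exclusion.excluded) or "none"))


if __name__ == "__main__":
    main()
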