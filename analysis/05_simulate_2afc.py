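#!/usr/bin/env python
"""Simulate the 2AFC contrast-discrimination cohort.

Eleven Bernoulli observers obeying the cumulative-Gaussian psychometric
function; twelve sessions of 36 trials each (9 test contrasts x 4 Chroma
conditions).  The group-mean sigma is largest under /2 (worst
discrimination with weakly saturated patches), and one observer is
generated with uniformly inflated sigma to exercise the exclusion rule.
"""

import argparse
from pathlib import Path

from chromasupp import io
from chromasupp.synthetic import study_2afc_cohort


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--subjects", type=int, default=11)
    parser.add_argument("--out", type=Path, default=Path("results/psycho"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trials = study_2afc_cohort(args.seed, n_subjects=args.subjects)
    io.write_trials(trials, args.out / "trials.csv")
    print(f"{args.subjects} observers x {trials['session'].max()} sessions "
          f"x {len(trials) // (args.subjects * trials['session'].max())} "
          f"trials = {len(trials)} trials -> {args.out / 'trials.csv'}")


if __name__ == "__main__":
    main()
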