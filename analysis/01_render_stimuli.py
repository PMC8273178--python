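#!/usr/bin/env python
"""Render the stimulus families of both experiments and verify photometry.

Writes example patch patterns (all four Chroma conditions, textured and
black backgrounds), scrambled counterparts, the enveloped grating at the
reference and extreme test contrasts, and the square mask, as 16-bit PNGs
with JSON sidecars; a summary CSV records the measured Michelson
contrasts and chip photometry.
"""

import argparse
from pathlib import Path

import pandas as pd

from chromasupp.munsell import chip_set, white_luminance_for_value5
from chromasupp.stimuli import (
    GratingSpec,
    PatchPatternSpec,
    TextureSpec,
    measure_michelson,
    render_grating,
    render_patch_pattern,
    render_texture,
    save_stimulus,
    scramble,
    PSYCHO_DISPLAY,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/stimuli"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for chroma in ("/0", "/2", "/4", "/6"):
        tag = chroma.strip("/")
        img = render_patch_pattern(
            PatchPatternSpec(chroma_condition=chroma), args.seed)
        save_stimulus(img, args.out / f"patches_{tag}")
        save_stimulus(scramble(img, args.seed + 1), args.out / f"scrambled_{tag}")
        ctrl = render_patch_pattern(
            PatchPatternSpec(chroma_condition=chroma, background="black"),
            args.seed)
        save_stimulus(ctrl, args.out / f"patches_{tag}_black")
        chips = chip_set(chroma, white_luminance_for_value5(16.0))
        rows.append({"stimulus": f"patches_{tag}",
                     "patch_luminance_cdm2": chips[0].luminance,
                     "distinct_hues": len({c.chromaticity for c in chips})})

    for contrast in (0.34, 0.50, 0.66):
        spec = GratingSpec(max_michelson_contrast=contrast)
        img = render_grating(spec, seed=args.seed)
        tag = f"grating_{int(100 * contrast)}"
        save_stimulus(img, args.out / tag)
        measured = measure_michelson(img, "grating")
        rows.append({"stimulus": tag, "nominal_contrast": contrast,
                     "measured_michelson": round(measured, 4)})
        print(f"{tag}: nominal {contrast:.2f}, measured {measured:.4f} "
              f"({100 * abs(measured - contrast) / contrast:.2f}% off)")

    mask = render_texture(TextureSpec.psycho_mask(), args.seed,
                          geometry=PSYCHO_DISPLAY)
    save_stimulus(mask, args.out / "mask")

    pd.DataFrame(rows).to_csv(args.out / "photometry_summary.csv", index=False)
    print(f"wrote stimulus set + photometry summary to {args.out}")


if __name__ == "__main__":
    main()
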