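"""Vector permutation test of parallel phenotypic change.

Builds one 2-D change vector per species and colonization event in
(predicted sensitivity index, species-relative cyp27c1) space — connecting
the ancestral to the derived population mean after per-axis
standardization — and tests whether the sums of the 21 pairwise differences
in vector direction and length are smaller than expected when species
identity is randomized within each environment (999 permutations; null
vectors connect single randomly drawn individuals).

Writes results/parallelism.tsv (one row per scope and statistic) and the
null distributions next to it.
"""

import argparse
from pathlib import Path

import pandas as pd

from opsinshift import parallelism

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--profiles", type=Path, default=ROOT / "results" / "profiles.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "parallelism.tsv")
    parser.add_argument("--n-perm", type=int, default=999)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--scale", choices=["sd", "none"], default="sd")
    parser.add_argument("--dump-null", action="store_true")
    args = parser.parse_args()

    profiles = pd.read_csv(args.profiles, sep="\t", index_col=0)
    frames = []
    nulls = {}
    for scope in parallelism.SCOPES:
        res = parallelism.permutation_test(
            profiles, scope=scope, n_perm=args.n_perm, seed=args.seed, scale=args.scale
        )
        frames.append(res.as_frame())
        nulls[f"{scope}.sum_angle"] = res.null_sum_angle
        nulls[f"{scope}.sum_length"] = res.null_sum_length
        print(
            f"{scope:15s} p_angle={res.p_angle:.4g}  p_length={res.p_length:.4g}  "
            f"(observed sums: angle={res.observed_sum_angle:.1f} deg, "
            f"length={res.observed_sum_length:.2f})"
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(args.out, sep="\t", index=False)
    if args.dump_null:
        pd.DataFrame(nulls).to_csv(args.out.with_suffix(".null.tsv"), sep="\t", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
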