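"""Behavior PLS of areal (de)coupling against age, with full inference.

Stacks the 33 subjects' S_C/S_D profiles into the 66 x 360 brain matrix,
correlates with age within group x condition cells, decomposes by SVD into
4 latent variables, and runs 10,000 age permutations plus 1,000 within-group
bootstrap resamples. Writes per-LV salience/BSR/CI tables, the network
summary, and the brain-score motion check to results/pls/.

Usage: python analysis/03_pls_brain_age.py [--seed 11] [--n-perm 10000]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neurocouple import io_formats as io
from neurocouple import pls_brain_age as pls
from neurocouple.cli import _load_profiles

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--n-boot", type=int, default=1000)
    args = ap.parse_args()

    subjects = io.read_subjects(ROOT / "results" / "subjects.tsv")
    network_of = io.read_labels(ROOT / "scratch" / "cohort" / "labels.tsv")
    profiles = _load_profiles(ROOT / "results" / "profiles.tsv", subjects)
    stack = pls.stack_cohort(profiles, subjects)
    print(f"brain matrix: {stack.brain.shape[0]} rows x "
          f"{stack.brain.shape[1]} areas; cells: {stack.cells}")

    result = pls.run_pls(stack, args.n_perm, args.n_boot,
                         network_of=network_of,
                         rng=np.random.default_rng(args.seed),
                         subjects=subjects)
    io.write_results(result, ROOT / "results" / "pls", network_of=network_of,
                     seed=args.seed)

    print("\nlatent variables:")
    for k in range(result.n_lv):
        p = result.perm_p[k]
        disp = f"< {1 / args.n_perm:g}" if p == 0 else f"{p:g}"
        print(f"  LV{k + 1}: singular value {result.singular_values[k]:.3f}, "
              f"permutation p {disp}")
        cells = ", ".join(f"{g}/{c} {v:+.2f}" for (g, c), v
                          in zip(result.cells, result.design_saliences[:, k]))
        print(f"        design saliences: {cells}")

    print("\nLV1 supra-threshold networks (|BSR| > 2.58):")
    summ = result.network_summaries[0]
    for net, cnt in sorted(summ.counts.items(), key=lambda kv: -kv[1]):
        if cnt:
            pos = summ.positive_mean.get(net)
            neg = summ.negative_mean.get(net)
            parts = [f"+{pos:.2f}" if pos is not None else None,
                     f"{neg:.2f}" if neg is not None else None]
            print(f"  {net}: {cnt} areas "
                  f"({', '.join(p for p in parts if p)})")

    print("\nbrain score vs head motion (should be small / non-significant):")
    print(result.motion.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
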