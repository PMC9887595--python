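#!/usr/bin/env python
"""Full-scale simulation study: 600×600 backgrounds, 100×100 implants.

Reproduces the original experiment sizes — six disjoint trend implants over
four replicates, and the overlap design at levels 0/30/40/50 — and prints
recovery/relevance per run.  Expect about ten minutes on one CPU; the desk
scale protocol in scripts/acceptance.py covers the same designs in about
one minute.

Usage:  python scripts/full_design.py [--seed 1] [--replicates 4]
"""

from __future__ import annotations

import argparse
import os
import sys
import time

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from arbic.benchmarks import FULL, overlap_spec, run_study, trend_spec  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=4)
    args = ap.parse_args()

    print("trend design (six 100x100 implants):")
    recs, rels = [], []
    for i in range(args.replicates):
        t0 = time.time()
        r = run_study(
            trend_spec(FULL, rng_seed=1000 * args.seed + i),
            pipeline_seed=args.seed,
        )
        recs.append(r.recovery)
        rels.append(r.relevance)
        print(
            f"  replicate {i}: recovery {r.recovery:.4f} relevance "
            f"{r.relevance:.4f} ({time.time() - t0:.0f}s)"
        )
    print(
        f"  mean recovery {sum(recs) / len(recs):.4f} "
        f"mean relevance {sum(rels) / len(rels):.4f}"
    )

    print("overlap design (levels 0/30/40/50):")
    for level in FULL.overlaps:
        t0 = time.time()
        r = run_study(
            overlap_spec(FULL, level, rng_seed=2000 * args.seed + level),
            pipeline_seed=args.seed,
        )
        print(
            f"  level {level}x{level}: recovery {r.recovery:.4f} relevance "
            f"{r.relevance:.4f} ({time.time() - t0:.0f}s)"
        )


if __name__ == "__main__":
    main()
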