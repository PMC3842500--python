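#!/usr/bin/env python
"""Two-level group inference: Poisson thresholds, then consistency counts.

Reads the per-participant connectivity matrices, fits each participant's
Poisson rate on their pooled seed-by-target values, thresholds at p = .05
(strictly-greater retention), counts surviving participants per connection,
applies the strict (>75%) and relaxed (>50%) consistency criteria, and
writes the group profile TSV — the machine-readable analogue of a
per-connection participant-count table.
"""

import argparse
from pathlib import Path

from pictract import io
from pictract.config import PipelineConfig
from pictract.group_stats import (
    PoissonModel,
    apply_individual_threshold,
    group_consistency,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--matrices", type=Path, default=Path("results/connectivity"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.cohort / "config_resolved.yaml")
    binaries, matrices = [], []
    for p in range(cfg.phantom.n_participants):
        m = io.read_matrix(
            args.matrices / f"connectivity_{p:02d}.tsv",
            n_initiated=cfg.tracking.n_streamlines_per_voxel,
        )
        model = PoissonModel.fit(m.values.ravel(), alpha=cfg.group.alpha)
        binaries.append(apply_individual_threshold(m, model))
        matrices.append(m)
        print(
            f"participant {p:02d}: lambda={model.lam:.1f} "
            f"threshold={model.threshold} "
            f"connections retained={int(binaries[-1].sum())}"
        )

    profile = group_consistency(
        binaries,
        matrices[0].seed_labels,
        matrices[0].target_labels,
        strict_frac=cfg.group.strict_frac,
        relaxed_frac=cfg.group.relaxed_frac,
    )
    path = io.write_profile(profile, args.out / "group_profile.tsv")
    df = profile.to_dataframe()
    hits = df[df.participant_count > 0]
    print(f"\ngroup profile ({profile.n_participants} participants, "
          f"strict >= {profile.strict_min}, relaxed >= {profile.relaxed_min}) "
          f"-> {path}")
    print(hits.to_string(index=False))


if __name__ == "__main__":
    main()
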