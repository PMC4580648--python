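"""Shared study configuration for the numbered analysis drivers.

One place defines the synthetic study conditions (22 pairs, 4 trials per
2 x 4 design cell, 60 s at 200 Hz) so every driver analyzes the same
deterministic dataset.  The anterior-posterior axis is the primary axis
throughout, matching the headline analyses.
"""

import argparse

from swaysync import StudyConfig


def build_config(seed: int, output_dir: str | None = None) -> StudyConfig:
    return StudyConfig(
        synth={"axes": ("AP",)},
        axes=("AP",),
        seed=seed,
        output_dir=output_dir,
    )


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1, help="study root seed")
    parser.add_argument(
        "--out", default="results", help="output directory for tables"
    )
    return parser.parse_args()
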