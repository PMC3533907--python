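"""Run configuration.

Defaults reproduce the method's published settings: identity thresholds 85%
down to 10% in steps of 5, neighbour thresholds 5.0-9.0 A in steps of 0.5,
candidate eligibility at >= 10 sequences, separation degree <= 3, 10,000
Monte Carlo permutations at the top-5% threshold, and a 9 A functional-region
radius.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    X_grid: list[float] = field(default_factory=lambda: [float(x) for x in range(85, 5, -5)])
    D_grid: list[float] = field(default_factory=lambda: [5.0 + 0.5 * k for k in range(9)])
    min_sequences: int = 10
    max_separation: int = 3
    n_perm: int = 10000
    alpha_fraction: float = 0.05
    seed: int = 0
    shell_spacing: float = 3.0
    shell_clash: float = 2.5
    shell_margin: float = 8.0
    aligner_command: list[str] = field(
        default_factory=lambda: ["mafft", "--auto", "--quiet"]
    )
    universe: str = "surface"  # or "all"
    region_radius: float = 9.0
    identity_floor: float = 0.95

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
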