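"""Run configuration: every tunable parameter of the descriptor pipeline.

The record is echoed into all output files so results carry full
provenance.  Defaults are the study conditions: 6 A AES neighborhood,
15 degree angular bins, 50 z-bins, normalized DDP, natural-log entropy,
mass-weighted center of mass.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    cutoff: float = 6.0          # A, AES neighborhood radius
    theta_bin: float = 15.0      # degrees
    phi_bin: float = 15.0        # degrees
    z_bins: int = 50             # DDP histogram bins
    ddp_mode: str = "normalized"  # {"normalized", "raw"}
    log_base: str = "e"          # {"e", "2"} for AES entropy
    com_mode: str = "mass"       # {"mass", "geometric"}
    lai_selection: str = "all_heavy"
    bond_scale: float = 1.15     # covalent-radius scale for bond inference
    hpc_helices_only: bool = False
    flip_normal: bool = False
    flip_torsion_sign: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ddp_mode not in ("normalized", "raw"):
            raise ValueError(f"ddp_mode {self.ddp_mode!r}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base {self.log_base!r}")
        if self.com_mode not in ("mass", "geometric"):
            raise ValueError(f"com_mode {self.com_mode!r}")
        if self.z_bins < 2:
            raise ValueError("z_bins must be >= 2")

    @property
    def log_base_value(self) -> float:
        return math.e if self.log_base == "e" else 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
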