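"""Model parameters for the coupled canonical/noncanonical NF-κB network.

The model tracks 14 species. Rate constants are in per-minute units,
abundances in arbitrary units (a.u.), and the two translational delays in
minutes. The shipped defaults are the calibrated nominal parameter set
(see :func:`nfkbcoupling.scan.calibrate_nominal`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Species names, in state-vector order.
SPECIES = (
    "IKK_active",
    "IkBa_mRNA",
    "IkBa_protein",
    "RelA_IkBa_complex",
    "RelA_nuclear",
    "CanonReporter_mRNA",
    "TRAF1_mRNA",
    "TRAF1_protein",
    "NIK_free",
    "TRAF1_NIK_complex",
    "p100_mRNA",
    "p100_protein",
    "p52",
    "TNIP1_mRNA",
)

N_SPECIES = len(SPECIES)

#: Nominal translational delays (minutes).
NOMINAL_TAU_TRAF1 = 120.0
NOMINAL_TAU_NFKB2 = 90.0

#: Largest admissible delay (minutes); the scans span 0-10 h.
MAX_DELAY_MIN = 600.0


@dataclass
class ModelParameters:
    """Rate constants and translational delays of the reduced network.

    Parameters default to the calibrated nominal set: a TNF step at t=0
    yields a canonical reporter peak within the first hour and a p52 onset
    (coupling interval at theta=0.10) of ~360 min at the nominal delays
    (120, 90) min, dropping to ~15 min when both delays are removed.
    """

    # translational delays (min)
    tau_traf1_min: float = NOMINAL_TAU_TRAF1
    tau_nfkb2_min: float = NOMINAL_TAU_NFKB2
    # canonical IKK module (per min)
    ikk_act_rate: float = 2.0
    ikk_inact_rate: float = 0.02
    # RelA-driven maximal transcription rates (a.u./min)
    txn_max_ikba: float = 1.2
    txn_max_traf1: float = 0.1243
    txn_max_p100: float = 0.13433
    txn_max_canon_reporter: float = 1.5
    # p52-driven transcription (a.u./min)
    txn_max_tnip1: float = 0.5
    txn_fb_p100: float = 1425.41
    txn_fb_traf1: float = 217.76
    # Hill form (promoter-specific half-saturation, a.u.)
    hill_K_rela: float = 0.3
    hill_K_p52: float = 0.66
    hill_K_p52_traf1: float = 3.08
    hill_h: float = 4.0
    # translation rates (per min)
    tln_rate_ikba: float = 1.0
    tln_rate_traf1: float = 0.4
    tln_rate_p100: float = 9.941
    # first-order decay (per min)
    deg_mrna: float = 1.0
    deg_ikba: float = 0.05
    deg_traf1: float = 0.4
    deg_p100: float = 3.5033
    deg_p52: float = 0.2136
    # NIK / TRAF1·NIK feed-forward module
    nik_synth_rate: float = 1.0
    nik_fast_deg: float = 1.0
    nik_stable_deg: float = 1.0
    traf1_nik_bind: float = 0.02
    proc_rate: float = 1.0
    proc_K: float = 0.02467
    # canonical IκBα/RelA shuttling
    ikba_rela_assoc: float = 2.0
    ikba_deg_by_ikk: float = 2.0
    rela_total: float = 1.0
    # constitutive transcription floor (a.u./min)
    basal_txn: float = 1e-06

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any out-of-range parameter."""
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.hill_h < 1:
            raise ValueError(f"hill_h must be >= 1, got {self.hill_h}")
        for name in ("tau_traf1_min", "tau_nfkb2_min"):
            v = getattr(self, name)
            if not 0 <= v <= MAX_DELAY_MIN:
                raise ValueError(f"{name} must lie in [0, {MAX_DELAY_MIN}] min, got {v}")
        if self.rela_total <= 0:
            raise ValueError("rela_total must be > 0")

    # -- conversion -------------------------------------------------------
    def replace(self, **kwargs) -> "ModelParameters":
        """Return a copy with some fields replaced (validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_array(self) -> np.ndarray:
        """Pack into a float array in field order (for the compiled core)."""
        return np.array(
            [getattr(self, f.name) for f in dataclasses.fields(self)], dtype=np.float64
        )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        names = cls.field_names()
        if len(arr) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(arr)}")
        return cls(**dict(zip(names, map(float, arr))))

    # -- flat key-value config io ----------------------------------------
    def to_config(self, path: str | Path) -> None:
        """Write a flat ``name = value`` config file (units in comments)."""
        lines = [
            "# nfkbcoupling model parameters",
            "# rates per minute, abundances in a.u., delays in minutes",
        ]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParameters":
        """Read a flat key-value config written by :meth:`to_config`."""
        values = parse_flat_config(path)
        known = set(cls.field_names())
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse ``name = value`` lines; '#' starts a comment; blanks ignored."""
    values: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return values


def default_parameters() -> ModelParameters:
    """The calibrated nominal parameter set shipped with the package."""
    cfg = Path(__file__).parent / "data" / "default_params.cfg"
    if cfg.exists():
        return ModelParameters.from_config(cfg)
    return ModelParameters()
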