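"""Model-faithful synthetic kinetics and peptide tables.

Generates the two kinds of tables the estimation code consumes, straight
from the model with optional measurement noise: per-bond hydrolyzed-fraction
time courses (the input of rate fitting) and peptide concentration-versus-
degree tables (the input of descriptor estimation).  Noise is additive
Gaussian on concentrations, truncated to the physical range, the way
chromatographic quantitation error enters such tables; every draw is
seeded and therefore reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree import BondInventory
from .descriptors import DEGREE_GRID
from .fitting import BondKineticsData
from .kinetics import bond_hydrolysis_fraction
from .study import STUDY_OVERRIDES, peptide_curves_on_grid
from .substrate import KD_DEFAULT, KDF_DEFAULT, SubstrateMap, load_substrate_table

#: default sampling grid (min) for bond time courses: six points spanning
#: the rise of a demasking-limited curve at kdf = 0.46 min^-1
DEFAULT_TIME_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


class SynthError(ValueError):
    """Raised for invalid synthetic-data specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """What to generate: substrate, rates, grid, noise model and seed."""

    substrate: SubstrateMap | None = None
    overrides: dict[int, float] = field(default_factory=lambda: dict(STUDY_OVERRIDES))
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    degree_grid: tuple[float, ...] = DEGREE_GRID
    noise_sd: float = 0.02
    seed: int = 0
    absolute_scale: bool = False  # emit concentrations x 50 (absolute units)
    kdf: float = KDF_DEFAULT
    kd: float = KD_DEFAULT

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be >= 0")

    def resolved_substrate(self) -> SubstrateMap:
        return self.substrate if self.substrate is not None else load_substrate_table()


def generate_bond_dataset(spec: SyntheticSpec) -> dict[str, BondKineticsData]:
    """Noisy hydrolyzed-fraction time courses for every active bond."""
    substrate = spec.resolved_substrate()
    inventory = BondInventory.from_substrate_map(
        substrate, spec.overrides, kdf=spec.kdf, kd=spec.kd
    )
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_grid, dtype=float)
    out = {}
    for bond in inventory.bonds:
        clean = bond_hydrolysis_fraction(
            bond.mechanism,
            spec.kdf,
            bond.k_abs,
            t,
            kd=spec.kd if bond.mechanism == "two_stage" else None,
        )
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
        out[bond.label] = BondKineticsData(
            label=bond.label,
            times=t,
            values=np.clip(noisy, 0.0, 1.0),
            noise_sd=spec.noise_sd or None,
        )
    return out


def bond_dataset_to_frame(dataset: dict[str, BondKineticsData]) -> pd.DataFrame:
    """Tidy (bond, t_min, value) view of a bond dataset."""
    records = [
        {"bond": label, "t_min": t, "value": v}
        for label, data in dataset.items()
        for t, v in zip(data.times, data.values)
    ]
    return pd.DataFrame.from_records(records)


def generate_peptide_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Peptide concentration-versus-degree table via the full pipeline.

    All nine intermediate and nine final study peptides on the degree grid,
    with optional noise and optional x50 absolute scaling (mirroring tables
    reported in absolute units that are divided by 50 on ingestion).
    """
    substrate = spec.resolved_substrate()
    frame = peptide_curves_on_grid(
        substrate, spec.degree_grid, spec.overrides, kdf=spec.kdf, kd=spec.kd
    ).copy()
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=len(frame))
        frame["concentration"] = np.clip(
            frame["concentration"].to_numpy() + noise, 0.0, None
        )
    if spec.absolute_scale:
        frame["concentration"] = frame["concentration"] * 50.0
    frame.attrs["seed"] = spec.seed
    frame.attrs["noise_sd"] = spec.noise_sd
    frame.attrs["absolute_scale"] = spec.absolute_scale
    return frame


def ingest_peptide_table(
    frame: pd.DataFrame, *, absolute: bool = False
) -> pd.DataFrame:
    """Normalise an external peptide table to relative concentrations.

    Tables declared ``absolute`` are divided by 50 to recover the relative
    per-chain scale.
    """
    out = frame.copy()
    if absolute:
        out["concentration"] = out["concentration"] / 50.0
    return out
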