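"""Cleavage map of the substrate and tryptic-site annotation.

The packaged map describes tryptic proteolysis of bovine beta-lactoglobulin
(beta-LG, 162 residues): one row per enzyme-specific peptide bond with its
selectivity, lag ratio, relative hydrolysis rate constant and demasking
class, plus the three trimeric regions whose fragment release the kinetic
schemes describe.  Coordinates are 1-based positions in the mature chain;
"bond j" is the bond following residue j, so fragment f(9-14) is released by
cleaving bonds 8 and 14.

Double-lysine sites (-Lys-Lys- at 69,70 and 100,101) are merged into single
sites labelled "69/70" and "100/101"; they carry the numeric keys 69 and 101
respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .kinetics import RateSet

#: reference hydrolysis rate constant k^8 = k_df, min^-1
K_REF = 0.46
#: first demasking rate constant, min^-1
KDF_DEFAULT = 0.46
#: second demasking rate constant (two-stage mechanism), min^-1
KD_DEFAULT = 0.15

#: beta-LG mature chain length (residues)
BLG_CHAIN_LENGTH = 162

DEMASK_CLASSES = ("one_stage", "two_stage", "excluded")

_TABLE_COLUMNS = [
    "bond_index",
    "label",
    "motif",
    "selectivity_pct",
    "lag_ratio",
    "k_rel",
    "demask_class",
    "is_fast",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class SubstrateError(ValueError):
    """Raised for malformed cleavage tables, regions or sequences."""


@dataclass(frozen=True)
class CleavageSite:
    """One enzyme-specific bond with its kinetic parameters.

    ``bond_index`` is the numeric key (P1 residue position); merged
    double-Lys sites keep a composite ``label`` such as ``"69/70"``.
    ``k_abs`` is the absolute hydrolysis rate constant in min^-1, by default
    ``k_rel * 0.46`` and zero for the excluded (non-hydrolyzable) class.
    """

    bond_index: int
    label: str
    motif: str
    selectivity_pct: float | None
    lag_ratio: float | None
    k_rel: float | None
    k_abs: float
    demask_class: str
    is_fast: bool

    def __post_init__(self) -> None:
        if self.demask_class not in DEMASK_CLASSES:
            raise SubstrateError(
                f"bond {self.label}: unknown demask_class {self.demask_class!r}"
            )
        if self.k_abs < 0:
            raise SubstrateError(f"bond {self.label}: k_abs must be >= 0")
        if self.selectivity_pct is not None and self.selectivity_pct < 0:
            raise SubstrateError(f"bond {self.label}: selectivity_pct must be >= 0")
        if self.lag_ratio is not None and self.lag_ratio < 0:
            raise SubstrateError(f"bond {self.label}: lag_ratio must be >= 0")
        if (self.demask_class == "excluded") != (self.k_abs == 0.0):
            raise SubstrateError(
                f"bond {self.label}: excluded class and k_abs = 0 must coincide"
            )


@dataclass(frozen=True)
class TrimerRegion:
    """An A|B|C block triple with two internal enzyme-specific bonds.

    Blocks are inclusive 1-based ``[start, end]`` intervals; the internal
    bonds are ``i`` at the A|B junction and ``j`` at the B|C junction.
    """

    blocks: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    bond_i: int
    bond_j: int
    mechanism: str

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1), (c0, c1) = self.blocks
        if self.mechanism not in ("one_stage", "two_stage"):
            raise SubstrateError(f"region: unknown mechanism {self.mechanism!r}")
        if not (a0 <= a1 < b0 <= b1 < c0 <= c1):
            raise SubstrateError(f"region blocks not ordered/contiguous: {self.blocks}")
        if a1 != self.bond_i or b0 != self.bond_i + 1:
            raise SubstrateError("A|B junction must coincide with bond_i")
        if b1 != self.bond_j or c0 != self.bond_j + 1:
            raise SubstrateError("B|C junction must coincide with bond_j")

    @property
    def internal_bonds(self) -> tuple[int, int]:
        return (self.bond_i, self.bond_j)

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[2][1])


@dataclass(frozen=True)
class SubstrateMap:
    """A validated cleavage map: sites plus trimeric regions."""

    chain_length: int
    sites: tuple[CleavageSite, ...]
    regions: tuple[TrimerRegion, ...] = ()

    def __post_init__(self) -> None:
        keys = [s.bond_index for s in self.sites]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise SubstrateError(f"duplicate bond indices: {sorted(dupes)}")
        for region in self.regions:
            for bond in region.internal_bonds:
                site = self.site(bond)
                if site is None:
                    raise SubstrateError(
                        f"region {region.span} references unknown bond {bond}"
                    )
                if site.demask_class == "excluded":
                    raise SubstrateError(
                        f"region {region.span} has excluded internal bond {bond}"
                    )

    @property
    def total_bonds(self) -> int:
        return self.chain_length - 1

    def site(self, bond_index: int) -> CleavageSite | None:
        for s in self.sites:
            if s.bond_index == bond_index:
                return s
        return None

    def active_sites(self) -> tuple[CleavageSite, ...]:
        """Sites with nonzero hydrolysis rate constant."""
        return tuple(s for s in self.sites if s.k_abs > 0)

    def region_for(self, span: tuple[int, int]) -> TrimerRegion:
        for r in self.regions:
            if r.span == span:
                return r
        raise SubstrateError(f"no region with span {span}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chain_length": self.chain_length,
            "sites": [asdict(s) for s in self.sites],
            "regions": [
                {
                    "blocks": [list(b) for b in r.blocks],
                    "bond_i": r.bond_i,
                    "bond_j": r.bond_j,
                    "mechanism": r.mechanism,
                }
                for r in self.regions
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SubstrateMap":
        sites = tuple(CleavageSite(**s) for s in payload["sites"])
        regions = tuple(
            TrimerRegion(
                blocks=tuple(tuple(b) for b in r["blocks"]),
                bond_i=r["bond_i"],
                bond_j=r["bond_j"],
                mechanism=r["mechanism"],
            )
            for r in payload.get("regions", ())
        )
        return cls(chain_length=payload["chain_length"], sites=sites, regions=regions)

    @classmethod
    def from_json(cls, path: str | Path) -> "SubstrateMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: trimeric regions of beta-LG: one one-stage region and two two-stage ones
_BLG_REGIONS = (
    TrimerRegion(((9, 14), (15, 40), (41, 69)), 14, 40, "one_stage"),
    TrimerRegion(((76, 83), (84, 91), (92, 101)), 83, 91, "two_stage"),
    TrimerRegion(((102, 124), (125, 135), (136, 138)), 124, 135, "two_stage"),
)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    return float(text)


def load_substrate_table(
    source: str | Path = "builtin:blg",
    *,
    chain_length: int | None = None,
    k_abs_overrides: Mapping[int, float] | None = None,
) -> SubstrateMap:
    """Load a cleavage map from the packaged table or a user TSV/JSON file.

    ``source`` may be ``"builtin:blg"`` (the packaged beta-LG/trypsin map,
    with its three trimeric regions attached), a path to a TSV with the same
    columns, or a path to a JSON file written by :meth:`SubstrateMap.to_json`.
    ``k_abs`` defaults to ``k_rel * 0.46`` min^-1 and to 0 for the excluded
    class; ``k_abs_overrides`` (bond index -> min^-1) takes precedence.
    """
    regions: tuple[TrimerRegion, ...] = ()
    if str(source) == "builtin:blg":
        with resources.as_file(
            resources.files("pepdemask.data") / "blg_trypsin.tsv"
        ) as path:
            frame = pd.read_csv(path, sep="\t", dtype=str)
        regions = _BLG_REGIONS
        chain_length = chain_length or BLG_CHAIN_LENGTH
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            return SubstrateMap.from_json(path)
        frame = pd.read_csv(path, sep="\t", dtype=str)
        chain_length = chain_length or BLG_CHAIN_LENGTH

    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing or frame.empty:
        raise SubstrateError(
            "cleavage table must have one row per site with columns "
            + ", ".join(_TABLE_COLUMNS)
            + (f"; missing: {missing}" if missing else "; table is empty")
        )

    overrides = dict(k_abs_overrides or {})
    sites = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            bond_index = int(str(row.bond_index).strip())
            demask_class = str(row.demask_class).strip()
            k_rel = _opt_float(row.k_rel)
            if bond_index in overrides:
                k_abs = float(overrides[bond_index])
            elif demask_class == "excluded":
                k_abs = 0.0
            else:
                if k_rel is None:
                    raise SubstrateError("k_rel required when no override given")
                k_abs = k_rel * K_REF
            motif = "" if pd.isna(row.motif) else str(row.motif).strip()
            sites.append(
                CleavageSite(
                    bond_index=bond_index,
                    label=str(row.label).strip(),
                    motif=motif,
                    selectivity_pct=_opt_float(row.selectivity_pct),
                    lag_ratio=_opt_float(row.lag_ratio),
                    k_rel=k_rel,
                    k_abs=k_abs,
                    demask_class=demask_class,
                    is_fast=_parse_bool(row.is_fast),
                )
            )
        except (ValueError, TypeError, SubstrateError) as exc:
            raise SubstrateError(f"malformed row {row_number} ({row!r}): {exc}") from exc

    return SubstrateMap(
        chain_length=chain_length, sites=tuple(sites), regions=regions
    )


def region_rates(
    substrate: SubstrateMap,
    region: TrimerRegion,
    overrides: Mapping[int, float] | None = None,
    *,
    kdf: float = KDF_DEFAULT,
    kd: float = KD_DEFAULT,
) -> RateSet:
    """Rate constants driving one trimeric region's release scheme.

    ``k_i``/``k_j`` come from ``overrides`` (bond index -> min^-1) when
    given, else from each site's ``k_abs``.  Two-stage regions carry the
    second demasking constant ``k_d``; one-stage regions do not.
    """
    if region not in substrate.regions:
        raise SubstrateError(f"region {region.span} does not belong to this map")
    overrides = dict(overrides or {})
    unknown = sorted(set(overrides) - set(region.internal_bonds))
    if unknown:
        raise SubstrateError(
            f"override for bonds {unknown} not internal to region {region.span}"
        )

    def bond_rate(bond: int) -> float:
        if bond in overrides:
            return float(overrides[bond])
        return substrate.site(bond).k_abs

    return RateSet(
        kdf=kdf,
        ki=bond_rate(region.bond_i),
        kj=bond_rate(region.bond_j),
        kd=kd if region.mechanism == "two_stage" else None,
    )


def annotate_cleavage_sites(sequence: str) -> list[int]:
    """Candidate tryptic cleavage positions in an amino-acid sequence.

    Returns 1-based P1 positions ``p`` where residue ``p`` is Lys or Arg,
    ``p`` is not the last residue, and residue ``p + 1`` is not Pro.
    """
    seq = sequence.strip().upper()
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in _AA]
    if bad:
        raise SubstrateError(f"non-standard residues at positions {bad}")
    return [
        p
        for p in range(1, len(seq))
        if seq[p - 1] in "KR" and seq[p] != "P"
    ]


def annotate_fasta(path: str | Path) -> dict[str, list[int]]:
    """Tryptic-site annotation for every record of a FASTA file."""
    from Bio import SeqIO

    return {
        record.id: annotate_cleavage_sites(str(record.seq))
        for record in SeqIO.parse(str(path), "fasta")
    }
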