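"""Core data containers shared by the simulation, reconstruction and mapping stages.

The package works with four central objects:

* :class:`FounderGenomes` — biallelic alleles of the 8 inbred founder strains at
  mapped markers, plus a focal interval in which one founder (CAST-like) carries
  private alleles.
* :class:`DiplotypeMosaic` — the ground-truth founder mosaic of one outbred
  mouse: per chromosome, two haplotypes, each a list of (start, end, founder)
  segments tiling the chromosome.
* :class:`HaplotypeDosage` — per mouse x marker, the expected number of copies
  (0..2) of each founder haplotype; rows sum to 2. Produced either from the
  truth (mosaic) or from the HMM posterior, and consumed by kinship, genome
  scans and the dominance test.
* :class:`VarianceComponents` — additive (kinship) and residual variances from
  the mixed-model fit, with the heritability ratio h2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

FOUNDER_IDS: tuple[str, ...] = tuple("ABCDEFGH")
N_FOUNDERS = 8

#: marker-map column names used by every reader/writer
MAP_COLUMNS = ("marker", "chr", "pos_Mb")

#: genotype call symbols: A = 0 copies of allele 1, H = 1, B = 2, N = missing
CALL_SYMBOLS = ("A", "H", "B", "N")


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check column names and strictly increasing positions within chromosome."""
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    for chrom, sub in marker_map.groupby("chr", sort=False):
        pos = sub["pos_Mb"].to_numpy(float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chr {chrom}")
    return marker_map


@dataclass(frozen=True)
class FounderGenomes:
    """Alleles of the eight founder strains at every mapped marker.

    ``alleles[m, f]`` is 0/1 for marker ``m`` and founder ``f`` (order matches
    ``founder_ids``).  ``private_interval`` = (chromosome, start_Mb, end_Mb) is
    the stretch where ``private_founder`` carries alleles absent from the other
    seven founders, emulating the wild-derived founder's private variation.
    """

    founder_ids: tuple[str, ...]
    alleles: np.ndarray
    marker_map: pd.DataFrame
    private_founder: str
    private_interval: tuple[int, float, float]

    def __post_init__(self) -> None:
        if len(self.founder_ids) != N_FOUNDERS:
            raise ValueError(f"exactly {N_FOUNDERS} founders required")
        if self.alleles.shape != (len(self.marker_map), N_FOUNDERS):
            raise ValueError("alleles shape must be (n_markers, 8)")
        if self.private_founder not in self.founder_ids:
            raise ValueError(f"unknown private founder {self.private_founder!r}")
        validate_marker_map(self.marker_map)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.marker_map["chr"]))

    def chromosome_length(self, chrom) -> float:
        pos = self.marker_map.loc[self.marker_map["chr"] == chrom, "pos_Mb"]
        if pos.empty:
            raise ValueError(f"chromosome {chrom} not on map")
        return float(pos.max())

    def markers_in(self, chrom, start_mb: float, end_mb: float) -> np.ndarray:
        """Indices of markers on ``chrom`` with start_mb <= pos <= end_mb."""
        m = self.marker_map
        sel = (m["chr"] == chrom) & (m["pos_Mb"] >= start_mb) & (m["pos_Mb"] <= end_mb)
        return np.flatnonzero(sel.to_numpy())


# One mosaic segment: (start_Mb, end_Mb, founder_label)
Segment = tuple[float, float, str]


@dataclass
class DiplotypeMosaic:
    """Ground-truth founder mosaic of one DO mouse.

    ``haplotypes[chrom]`` holds two segment lists (one per haplotype); segments
    tile the chromosome exactly, in order, with no gaps.
    """

    mouse_id: str
    generation: int
    haplotypes: dict

    def n_breakpoints(self, chrom=None) -> int:
        """Number of segment boundaries (mosaic breakpoints) over both haplotypes."""
        chroms = [chrom] if chrom is not None else list(self.haplotypes)
        return sum(len(h) - 1 for c in chroms for h in self.haplotypes[c])

    def founder_pair_at(self, chrom, pos_mb: float) -> tuple[str, str]:
        pair = []
        for hap in self.haplotypes[chrom]:
            for start, end, founder in hap:
                if start <= pos_mb <= end:
                    pair.append(founder)
                    break
            else:  # pos beyond last segment end by float fuzz
                pair.append(hap[-1][2])
        return tuple(pair)


@dataclass
class TrueQtlSpec:
    """A planted QTL: locus, focal founder, mode of action and effect size.

    ``effect_size`` is the allele effect on the log-response scale; when None
    the simulator sizes it so the QTL explains ``var_frac`` of the phenotypic
    variance at the top exposure concentration. ``protective`` gives the
    effect a negative sign (carriers show less chromosomal damage).
    """

    chromosome: int
    position_mb: float
    focal_founder: str = "F"
    mode: str = "dominant"
    protective: bool = True
    effect_size: float | None = None
    var_frac: float = 0.49

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominant"):
            raise ValueError(f"mode must be additive or dominant, got {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "position_mb": self.position_mb,
            "focal_founder": self.focal_founder,
            "mode": self.mode,
            "protective": self.protective,
            "effect_size": self.effect_size,
            "var_frac": self.var_frac,
        }


@dataclass
class HaplotypeDosage:
    """Expected founder-haplotype copy numbers per mouse and marker.

    ``dosages`` has shape (n_mice, n_markers, 8); each (mouse, marker) row is
    non-negative and sums to 2 (two haplotypes).
    """

    mouse_ids: list
    marker_map: pd.DataFrame
    dosages: np.ndarray
    founder_ids: tuple[str, ...] = FOUNDER_IDS

    def __post_init__(self) -> None:
        n, m, f = self.dosages.shape
        if n != len(self.mouse_ids) or m != len(self.marker_map) or f != N_FOUNDERS:
            raise ValueError("dosage array shape inconsistent with ids/map")

    def validate(self, atol: float = 1e-8) -> None:
        if np.any(self.dosages < -atol) or np.any(self.dosages > 2 + atol):
            raise ValueError("dosages outside [0, 2]")
        sums = self.dosages.sum(axis=2)
        if not np.allclose(sums, 2.0, atol=atol):
            raise ValueError("dosage rows must sum to 2")

    def subset_mice(self, mouse_ids: Sequence) -> "HaplotypeDosage":
        index = {m: i for i, m in enumerate(self.mouse_ids)}
        unknown = [m for m in mouse_ids if m not in index]
        if unknown:
            raise KeyError(f"unknown mice: {unknown[:5]}")
        rows = [index[m] for m in mouse_ids]
        return HaplotypeDosage(
            list(mouse_ids), self.marker_map, self.dosages[rows], self.founder_ids
        )

    def founder_dosage_at(self, chrom, pos_mb: float, founder: str) -> np.ndarray:
        """Dosage of one founder at the marker nearest (chrom, pos_mb), per mouse."""
        sub = self.marker_map.index[self.marker_map["chr"] == chrom]
        if len(sub) == 0:
            raise ValueError(f"chromosome {chrom} not on map")
        pos = self.marker_map.loc[sub, "pos_Mb"].to_numpy(float)
        j = sub[np.argmin(np.abs(pos - pos_mb))]
        f = self.founder_ids.index(founder)
        return self.dosages[:, self.marker_map.index.get_loc(j), f]

    def to_long(self) -> pd.DataFrame:
        """Long-format frame (mouse, marker, founder, dosage)."""
        n, m, f = self.dosages.shape
        markers = self.marker_map["marker"].to_numpy()
        return pd.DataFrame(
            {
                "mouse": np.repeat(self.mouse_ids, m * f),
                "marker": np.tile(np.repeat(markers, f), n),
                "founder": np.tile(self.founder_ids, n * m),
                "dosage": self.dosages.reshape(-1),
            }
        )

    @classmethod
    def from_long(
        cls, frame: pd.DataFrame, marker_map: pd.DataFrame
    ) -> "HaplotypeDosage":
        mice = list(pd.unique(frame["mouse"]))
        markers = marker_map["marker"].to_numpy()
        wide = frame.pivot_table(
            index="mouse", columns=["marker", "founder"], values="dosage", sort=False
        )
        arr = np.empty((len(mice), len(markers), N_FOUNDERS))
        for i, mouse in enumerate(mice):
            for j, marker in enumerate(markers):
                for k, f in enumerate(FOUNDER_IDS):
                    arr[i, j, k] = wide.loc[mouse, (marker, f)]
        return cls(mice, marker_map, arr)


@dataclass
class VarianceComponents:
    """Additive and residual variance components from the kinship mixed model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    method: str = "reml"

    def to_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "h2": self.h2,
            "loglik": self.loglik,
            "method": self.method,
        }

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"VarianceComponents(sigma_g2={self.sigma_g2:.4g}, "
            f"sigma_e2={self.sigma_e2:.4g}, h2={self.h2:.3f})"
        )


def dumps_json(obj: dict) -> str:
    """JSON dump with numpy scalars coerced to Python floats/ints."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(obj, indent=2, default=default)
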