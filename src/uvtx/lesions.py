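"""Poisson model of UV photolesions on a gene.

UVC light deposits cyclobutane pyrimidine dimers and other transcription-
blocking photoproducts essentially independently along the DNA, so lesion
counts per region are Poisson and positions are uniform.  The calibration
used throughout: 10 J/m2 of UVC produces on average one transcription-
blocking lesion per 14 kb of a single strand (one per 7 kbp of duplex),
scaling linearly with dose.  CPDs and 6-4 photoproducts are pooled into a
single blocking-lesion density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Gene, ParameterError

__all__ = [
    "LesionField",
    "StateError",
    "lesion_density",
    "place_lesions",
    "lesion_class_probabilities",
    "expected_readthrough",
    "lesion_field_to_frame",
    "lesion_field_from_frame",
    "REFERENCE_DOSE",
    "BP_PER_LESION_PER_STRAND",
]

#: 10 J/m2 gives 1 blocking lesion per 14 kb on each strand.
REFERENCE_DOSE = 10.0
BP_PER_LESION_PER_STRAND = 14_000.0


class StateError(RuntimeError):
    """Operation requires state (e.g. removal times) that is not yet set."""


@dataclass
class LesionField:
    """Lesion positions on both strands of one gene, with removal times.

    Positions are bp offsets from the TSS, sorted ascending per strand.
    ``ts`` is the transcribed (template) strand — the strand whose lesions
    arrest elongating RNA polymerase II; ``nts`` the non-transcribed strand.
    Removal times are hours post-irradiation, +inf until a repair model
    assigns them.
    """

    gene_id: str
    ts_positions: np.ndarray
    nts_positions: np.ndarray
    density: float
    ts_removal: np.ndarray = field(default=None)  # type: ignore[assignment]
    nts_removal: np.ndarray = field(default=None)  # type: ignore[assignment]
    removal_assigned: bool = False

    def __post_init__(self) -> None:
        self.ts_positions = np.sort(np.asarray(self.ts_positions, dtype=float))
        self.nts_positions = np.sort(np.asarray(self.nts_positions, dtype=float))
        if self.density < 0:
            raise ParameterError("density must be >= 0")
        if self.ts_removal is None:
            self.ts_removal = np.full(self.ts_positions.size, np.inf)
        if self.nts_removal is None:
            self.nts_removal = np.full(self.nts_positions.size, np.inf)
        self.ts_removal = np.asarray(self.ts_removal, dtype=float)
        self.nts_removal = np.asarray(self.nts_removal, dtype=float)
        if self.ts_removal.shape != self.ts_positions.shape:
            raise ParameterError("one removal time per transcribed-strand lesion required")
        if self.nts_removal.shape != self.nts_positions.shape:
            raise ParameterError("one removal time per non-transcribed-strand lesion required")
        if np.any(self.ts_removal < 0) or np.any(self.nts_removal < 0):
            raise ParameterError("removal times must be >= 0")

    @property
    def n_lesions(self) -> int:
        return self.ts_positions.size + self.nts_positions.size


def lesion_density(dose: float) -> float:
    """Per-bp per-strand blocking-lesion density at a given UVC dose (J/m2).

    Linear in dose: 10 J/m2 -> 1/14000 per bp per strand.
    """
    if dose < 0:
        raise ParameterError("dose must be >= 0")
    return dose / REFERENCE_DOSE / BP_PER_LESION_PER_STRAND


def place_lesions(gene: Gene, density: float, seed) -> LesionField:
    """Place Poisson(density * length) lesions uniformly on each strand."""
    if density < 0:
        raise ParameterError("density must be >= 0")
    rng = np.random.default_rng(seed)
    lam = density * gene.length
    n_ts, n_nts = rng.poisson(lam, size=2)
    return LesionField(
        gene_id=gene.id,
        ts_positions=rng.uniform(0, gene.length, n_ts),
        nts_positions=rng.uniform(0, gene.length, n_nts),
        density=density,
    )


def lesion_class_probabilities(gene_length: float, density: float, k_max: int) -> np.ndarray:
    """P(0), ..., P(k_max - 1) lesions and the tail P(k >= k_max) for one gene.

    Counts are Poisson with mean gene_length * density (one strand).  The
    returned array has k_max + 1 entries and sums to 1 exactly.
    """
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if gene_length < 0 or density < 0:
        raise ParameterError("gene_length and density must be >= 0")
    lam = gene_length * density
    p = stats.poisson.pmf(np.arange(k_max), lam)
    return np.append(p, 1.0 - p.sum())


def expected_readthrough(x, density: float):
    """Probability a polymerase starting at the TSS reaches position x
    immediately after irradiation: exp(-density * x), i.e. no transcribed-
    strand lesion in [0, x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("x must be >= 0")
    if density < 0:
        raise ParameterError("density must be >= 0")
    out = np.exp(-density * x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# TSV serialization (gene_id, strand, position, removal_time)
# ---------------------------------------------------------------------------

def lesion_field_to_frame(fld: LesionField) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": fld.gene_id,
            "strand": ["TS"] * fld.ts_positions.size + ["NTS"] * fld.nts_positions.size,
            "position": np.concatenate([fld.ts_positions, fld.nts_positions]),
            "removal_time": np.concatenate([fld.ts_removal, fld.nts_removal]),
        }
    )


def lesion_field_from_frame(df: pd.DataFrame, density: float, removal_assigned: bool = True) -> LesionField:
    ts = df[df["strand"] == "TS"].sort_values("position")
    nts = df[df["strand"] == "NTS"].sort_values("position")
    gene_ids = df["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ParameterError("frame must contain exactly one gene_id")
    return LesionField(
        gene_id=str(gene_ids[0]),
        ts_positions=ts["position"].to_numpy(),
        nts_positions=nts["position"].to_numpy(),
        density=density,
        ts_removal=ts["removal_time"].to_numpy(),
        nts_removal=nts["removal_time"].to_numpy(),
        removal_assigned=removal_assigned,
    )
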