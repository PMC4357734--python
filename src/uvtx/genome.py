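"""Gene and coverage containers, the synthetic gene-set generator, and BED /
bedGraph / TSV input-output.

Coordinates are 0-based half-open throughout.  Gene-local coordinates put the
transcription start site (TSS) at 0 irrespective of strand; strand is resolved
only when coverage is projected to or from genomic (bedGraph) coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GeneSet",
    "Condition",
    "CoverageTrack",
    "ParameterError",
    "BedParseError",
    "generate_gene_set",
    "read_genes",
    "write_genes",
    "read_rpkm_table",
    "write_rpkm_table",
    "set_rates_from_rpkm",
    "write_coverage",
    "read_coverage",
    "n_bins",
]

MIN_GENE_LENGTH = 200
LENGTH_CLIP = (1_000, 1_000_000)  # bp, generator clip bounds


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class BedParseError(ValueError):
    """A BED/bedGraph line could not be parsed; message names the line."""


@dataclass(frozen=True)
class Gene:
    """A transcription unit.

    ``basal_rate`` is the initiation rate in events per minute, expressed in
    RPKM-equivalent units (the simulator calibrates its library size so that
    control RPKM of a gene equals its basal rate).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    basal_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"gene {self.id}: end ({self.end}) <= start ({self.start})")
        if self.length < MIN_GENE_LENGTH:
            raise ParameterError(f"gene {self.id}: length {self.length} < {MIN_GENE_LENGTH} bp")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not (self.basal_rate >= 0):
            raise ParameterError(f"gene {self.id}: basal_rate must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site."""
        return self.start if self.strand == "+" else self.end


class GeneSet:
    """An ordered, id-unique collection of genes.

    Overlapping genes are tolerated with a warning (the simulator treats
    genes independently); the generator never produces overlaps.
    """

    def __init__(self, genes: Iterable[Gene], provenance: str = "") -> None:
        self.genes: list[Gene] = list(genes)
        self.provenance = provenance
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate gene ids: {dup[:5]}")
        self._by_id = {g.id: g for g in self.genes}
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    warnings.warn(
                        f"overlapping genes on {chrom}: {a.id} and {b.id}", stacklevel=3
                    )
                    return

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSet) and self.genes == other.genes

    def ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def lengths(self) -> pd.Series:
        return pd.Series({g.id: g.length for g in self.genes}, name="length")


class Condition(NamedTuple):
    """One experimental condition: UV dose, recovery time, repair genotype."""

    dose: float  # J/m^2
    time_h: float  # hours between irradiation and labeling
    genotype: str

    @property
    def label(self) -> str:
        dose = f"{self.dose:g}Jm2"
        return f"{self.genotype}_{dose}_{self.time_h:g}h"


def n_bins(length: int, bin_width: int) -> int:
    return math.ceil(length / bin_width)


@dataclass
class CoverageTrack:
    """Binned nascent-RNA read counts over gene-local coordinates (TSS = 0)."""

    gene_id: str
    bin_width: int
    counts: np.ndarray
    library_size: float
    condition: Condition

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ParameterError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")
        if not self.library_size > 0:
            raise ParameterError("library_size must be positive")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# Synthetic gene set
# ---------------------------------------------------------------------------

#: Defaults emulate a mammalian annotation: log-normal lengths spanning
#: ~1 kbp to ~1 Mbp, and an expression distribution with a large silent
#: fraction (overall mean ~1.09, overall median ~0.15 RPKM-equivalents).
DEFAULT_LENGTH_LOG_MEAN = math.log(30_000)
DEFAULT_LENGTH_LOG_SD = 1.2
DEFAULT_EXPRESSION_SHAPE = 0.64
DEFAULT_EXPRESSION_SCALE = 2.84
DEFAULT_SILENT_FRACTION = 0.40
_INTERGENIC_GAP = 10_000  # bp between consecutive synthetic genes


def generate_gene_set(
    n_genes: int,
    length_log_mean: float = DEFAULT_LENGTH_LOG_MEAN,
    length_log_sd: float = DEFAULT_LENGTH_LOG_SD,
    expression_shape: float = DEFAULT_EXPRESSION_SHAPE,
    expression_scale: float = DEFAULT_EXPRESSION_SCALE,
    silent_fraction: float = DEFAULT_SILENT_FRACTION,
    seed: int = 0,
) -> GeneSet:
    """Draw a non-overlapping synthetic gene set on one synthetic chromosome.

    Lengths are log-normal, clipped to [1 kbp, 1 Mbp]; basal initiation rates
    are zero with probability ``silent_fraction`` and Gamma(shape, scale)
    otherwise.  Identical seeds yield identical sets.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    for name, v in [
        ("length_log_mean", length_log_mean),
        ("length_log_sd", length_log_sd),
        ("expression_shape", expression_shape),
        ("expression_scale", expression_scale),
    ]:
        if not v > 0:
            raise ParameterError(f"{name} must be positive")
    if not 0 <= silent_fraction < 1:
        raise ParameterError("silent_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.normal(length_log_mean, length_log_sd, n_genes))
    lengths = np.clip(np.rint(lengths).astype(int), *LENGTH_CLIP)
    silent = rng.random(n_genes) < silent_fraction
    rates = rng.gamma(expression_shape, expression_scale, n_genes)
    rates[silent] = 0.0
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

    genes = []
    cursor = _INTERGENIC_GAP
    width = len(str(n_genes))
    for i in range(n_genes):
        genes.append(
            Gene(
                id=f"g{i + 1:0{width}d}",
                chrom="chrS",
                start=cursor,
                end=cursor + int(lengths[i]),
                strand=str(strands[i]),
                basal_rate=float(rates[i]),
            )
        )
        cursor += int(lengths[i]) + _INTERGENIC_GAP
    prov = (
        f"generate_gene_set(n_genes={n_genes}, length_log_mean={length_log_mean:.6g}, "
        f"length_log_sd={length_log_sd:g}, expression_shape={expression_shape:g}, "
        f"expression_scale={expression_scale:g}, silent_fraction={silent_fraction:g}, "
        f"seed={seed})"
    )
    return GeneSet(genes, provenance=prov)


# ---------------------------------------------------------------------------
# BED genes
# ---------------------------------------------------------------------------

def read_genes(path) -> GeneSet:
    """Read a BED6 or BED12 file into a :class:`GeneSet`.

    BED12 thick/block columns are ignored.  A numeric score column is
    interpreted as the basal initiation rate (a plain annotation's score of 0
    or "." yields rate 0); rates may instead be attached later from an RPKM
    table via :func:`set_rates_from_rpkm`.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(parts)}")
            chrom, start_s, end_s, name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            try:
                rate = max(0.0, float(score_s))
            except ValueError:
                rate = 0.0
            try:
                genes.append(Gene(name, chrom, start, end, strand, rate))
            except ParameterError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneSet(genes, provenance=str(path))


def write_genes(gene_set: GeneSet, path) -> str:
    """Write a GeneSet as BED6; the score column carries the basal rate."""
    with open(path, "w") as fh:
        for g in gene_set:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t{g.basal_rate:.10g}\t{g.strand}\n")
    return str(path)


def read_rpkm_table(path) -> pd.Series:
    """Read a two-column TSV (gene_id, rpkm) into a Series indexed by id."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "rpkm"} <= set(df.columns):
        raise BedParseError(f"{path}: expected columns gene_id, rpkm")
    return df.set_index("gene_id")["rpkm"].astype(float)


def write_rpkm_table(rpkm: Mapping[str, float] | pd.Series, path) -> str:
    s = pd.Series(dict(rpkm) if not isinstance(rpkm, pd.Series) else rpkm, name="rpkm")
    s.rename_axis("gene_id").to_frame().to_csv(path, sep="\t")
    return str(path)


def set_rates_from_rpkm(gene_set: GeneSet, rpkm: Mapping[str, float] | pd.Series) -> GeneSet:
    """Return a new GeneSet with basal rates taken from an RPKM table."""
    genes = [replace(g, basal_rate=float(rpkm.get(g.id, g.basal_rate))) for g in gene_set]
    return GeneSet(genes, provenance=gene_set.provenance + " + rpkm table")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def _bin_genomic_interval(gene: Gene, k: int, bin_width: int) -> tuple[int, int]:
    """Genomic (start, end) of gene-local bin ``k`` (bin 0 anchored at TSS)."""
    if gene.strand == "+":
        s = gene.start + k * bin_width
        e = min(gene.start + (k + 1) * bin_width, gene.end)
    else:
        e = gene.end - k * bin_width
        s = max(gene.end - (k + 1) * bin_width, gene.start)
    return s, e


def write_coverage(tracks: Sequence[CoverageTrack] | Mapping[str, CoverageTrack],
                   gene_set: GeneSet, path) -> str:
    """Write coverage tracks for one condition as bedGraph.

    Bin 0 of each track sits at the gene's TSS; minus-strand bins are emitted
    in ascending genomic order.  Header comments record bin width, library
    size and condition so that :func:`read_coverage` can round-trip.
    """
    if isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    if not tracks:
        raise ParameterError("no tracks to write")
    bw = tracks[0].bin_width
    cond = tracks[0].condition
    lib = tracks[0].library_size
    if any(t.bin_width != bw for t in tracks):
        raise ParameterError("tracks must share bin_width")
    lines: list[tuple[str, int, int, float]] = []
    for t in tracks:
        gene = gene_set[t.gene_id]
        if len(t.counts) != n_bins(gene.length, bw):
            raise ParameterError(f"{t.gene_id}: bin count mismatch with gene length")
        for k, v in enumerate(t.counts):
            s, e = _bin_genomic_interval(gene, k, bw)
            lines.append((gene.chrom, s, e, float(v)))
    lines.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(f"# bin_width={bw}\n# library_size={lib:.10g}\n")
        fh.write(f"# condition={cond.dose:g},{cond.time_h:g},{cond.genotype}\n")
        for chrom, s, e, v in lines:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
    return str(path)


def read_coverage(path, gene_set: GeneSet) -> dict[str, CoverageTrack]:
    """Read a bedGraph written by :func:`write_coverage` back into tracks."""
    bw = lib = cond = None
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "bin_width":
                    bw = int(val)
                elif key == "library_size":
                    lib = float(val)
                elif key == "condition":
                    d, t, g = val.split(",")
                    cond = Condition(float(d), float(t), g)
                continue
            parts = line.split()
            if len(parts) != 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
    if bw is None or lib is None or cond is None:
        raise BedParseError(f"{path}: missing bin_width/library_size/condition header")

    # genomic interval -> owning gene, via per-chromosome sorted starts
    by_chrom: dict[str, list[Gene]] = {}
    for g in gene_set:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)
    index = {c: (np.array([g.start for g in gs]), gs) for c, gs in by_chrom.items()}

    counts: dict[str, np.ndarray] = {}
    for chrom, s, e, v in rows:
        starts, gs = index[chrom]
        i = int(np.searchsorted(starts, s, side="right")) - 1
        if i < 0 or s >= gs[i].end:
            raise BedParseError(f"{path}: interval {chrom}:{s}-{e} not inside any gene")
        gene = gs[i]
        if gene.id not in counts:
            counts[gene.id] = np.zeros(n_bins(gene.length, bw))
        k = (s - gene.start) // bw if gene.strand == "+" else (gene.end - e) // bw
        counts[gene.id][k] += v
    return {
        gid: CoverageTrack(gid, bw, c, library_size=lib, condition=cond)
        for gid, c in counts.items()
    }
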