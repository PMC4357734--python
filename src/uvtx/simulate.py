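"""Mechanistic simulator of bromouridine-labeled nascent-RNA coverage.

The model: RNA polymerase II complexes initiate at the TSS as a Poisson
process at the gene's basal rate and elongate at constant speed.  A
polymerase arrests permanently at the first transcribed-strand lesion that
is still unrepaired when the polymerase reaches it — no resumption and no
translesion bypass, so after repair of a lesion all new synthesis downstream
of it must come from freshly initiated polymerases.  Bromouridine marks only
RNA polymerized inside the labeling window, so a polymerase contributes
coverage exactly over the interval it traverses during the window;
polymerases already in transit when the window opens (initiated up to
length/speed earlier) supply the 3'-end coverage of long genes.

The pre-window occupancy is the post-irradiation quasi-steady state: the
arrest rule is applied to pre-window initiations as if the lesion field had
always been present, so a polymerase found at position x at window start
implies no lesion blocked [0, x) on its way there.  The short transient of
elongation complexes that were already beyond lesion positions at the
moment of irradiation is deliberately not modeled (those complexes are
assumed displaced at lesion-containing genes); immediately after UV this
makes body coverage decay as exp(-density * x), the target-theory form.

Coverage is computed as the *expected* labeled mass per bin given one lesion
realization (the initiation process is integrated out), and sequencing is
emulated by multinomial sampling of a fixed read total across all bins of
all genes — read counts are therefore compositional, as in a real library.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Condition,
    CoverageTrack,
    Gene,
    GeneSet,
    ParameterError,
    n_bins,
    write_coverage,
    write_rpkm_table,
)
from .lesions import LesionField, StateError, lesion_density, place_lesions
from .repair import (
    DEFAULT_GG_RATE,
    DEFAULT_TC_WAVE_SPEED,
    RepairParams,
    assign_removal_times,
    genotype_presets,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_bru_window",
    "arrest_position",
    "sample_reads",
    "simulate_experiment",
    "write_outputs",
]


@dataclass
class SimulationConfig:
    """Experimental grid and physical constants for one simulation run."""

    doses: tuple[float, ...] = (10.0,)  # J/m2; dose 0 control always added
    timepoints: tuple[float, ...] = (0.0, 6.0, 24.0)  # hours post-UV
    genotypes: tuple[str, ...] = ("WT",)
    label_window: float = 30.0  # minutes of bromouridine labeling
    elongation_speed: float = 1_500.0  # bp per minute
    reads_per_condition: int = 1_000_000
    bin_width: int = 500
    tc_wave_speed: float = DEFAULT_TC_WAVE_SPEED
    gg_rate: float = DEFAULT_GG_RATE
    restart_competence: dict[str, bool] = dc_field(default_factory=dict)
    seed: int = 0
    tau_step: float = 0.5  # minutes; initiation-time quadrature step

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.genotypes = tuple(self.genotypes)
        if not self.label_window > 0:
            raise ParameterError("label_window must be > 0")
        if not self.elongation_speed > 0:
            raise ParameterError("elongation_speed must be > 0")
        if self.reads_per_condition < 1:
            raise ParameterError("reads_per_condition must be >= 1")
        if self.bin_width < 1:
            raise ParameterError("bin_width must be >= 1")
        if not self.tau_step > 0:
            raise ParameterError("tau_step must be > 0")
        if any(d < 0 for d in self.doses) or any(t < 0 for t in self.timepoints):
            raise ParameterError("doses and timepoints must be >= 0")
        for name, vals in [("doses", self.doses), ("timepoints", self.timepoints),
                           ("genotypes", self.genotypes)]:
            if len(set(vals)) != len(vals):
                raise ParameterError(f"duplicate entries in {name}: {vals}")

    def repair_params(self, genotype: str) -> RepairParams:
        return genotype_presets(genotype, self.tc_wave_speed, self.gg_rate)


def _effective_removal_minutes(field: LesionField, restart_competent: bool) -> np.ndarray:
    """Transcribed-strand removal times in minutes as seen by polymerases.

    A restart-incompetent gene behaves as if its lesions were never cleared
    from the template the polymerase reads: repair proceeds, synthesis does
    not resume (the SLIT2-like phenotype).
    """
    if restart_competent:
        return field.ts_removal * 60.0
    return np.full(field.ts_positions.size, np.inf)


def arrest_position(
    field: LesionField,
    tau_minutes: float,
    elongation_speed: float,
    restart_competent: bool = True,
) -> float:
    """Arrest position (bp from TSS) of a single polymerase initiating at
    ``tau_minutes`` relative to irradiation, or +inf if it never arrests.

    A lesion at offset x blocks iff it is unrepaired when the polymerase
    passes it (tau + x/v < removal time).  The rule is applied to pre-window
    initiations as well, so the occupancy at any window start is the
    post-irradiation quasi-steady state (see module docstring).
    """
    if not field.removal_assigned:
        raise StateError("removal times have not been assigned")
    v = elongation_speed
    x = field.ts_positions
    r = _effective_removal_minutes(field, restart_competent)
    blocking = tau_minutes < r - x / v
    return float(x[blocking].min()) if blocking.any() else np.inf


def simulate_bru_window(
    gene: Gene,
    field: LesionField,
    t_start_hours: float,
    config: SimulationConfig,
    restart_competent: bool | None = None,
) -> np.ndarray:
    """Expected labeled-RNA mass per bin for one gene and one timepoint.

    Integrates the Poisson initiation process over initiation times from
    ``t_start - length/speed`` (pre-window equilibrium, including pre-UV
    initiations) to the end of the window, with each polymerase arresting at
    the first lesion unrepaired at its passage time and depositing mass over
    the interval it polymerizes inside the window.
    """
    if not field.removal_assigned:
        raise StateError("removal times have not been assigned")
    if field.gene_id != gene.id:
        raise ParameterError(f"field belongs to {field.gene_id!r}, not {gene.id!r}")
    if restart_competent is None:
        restart_competent = config.restart_competence.get(gene.id, True)

    L = float(gene.length)
    bw = config.bin_width
    nb = n_bins(gene.length, bw)
    if gene.basal_rate == 0:
        return np.zeros(nb)

    v = config.elongation_speed
    t0 = t_start_hours * 60.0
    t1 = t0 + config.label_window
    dt = config.tau_step

    # midpoint quadrature over initiation times
    tau = np.arange(t0 - L / v, t1, dt) + dt / 2.0

    x = field.ts_positions
    r = _effective_removal_minutes(field, restart_competent)
    stop = np.full(tau.size, np.inf)
    if x.size:
        # lesion i blocks initiation time tau iff tau < c_i; the arrest
        # position is the nearest blocking lesion: min x_i over {c_i > tau}
        c = r - x / v
        order = np.argsort(c, kind="stable")
        c_sorted = c[order]
        sufmin = np.minimum.accumulate(x[order][::-1])[::-1]
        sufmin = np.append(sufmin, np.inf)
        idx = np.searchsorted(c_sorted, tau, side="right")
        stop = sufmin[idx]

    exit_ = np.minimum(np.minimum(stop, v * (t1 - tau)), L)
    entry = np.clip(v * (t0 - tau), 0.0, None)
    live = exit_ > entry
    if not live.any():
        return np.zeros(nb)

    # per-bin mass from sum of intervals [entry, exit): evaluate the
    # cumulative mass F(e) = sum_i clip(e - a_i, 0, b_i - a_i) at bin edges
    sa = np.sort(entry[live])
    sb = np.sort(exit_[live])
    csa = np.concatenate([[0.0], np.cumsum(sa)])
    csb = np.concatenate([[0.0], np.cumsum(sb)])
    edges = np.minimum(bw * np.arange(nb + 1, dtype=float), L)

    def ramp_sum(e: np.ndarray, arr: np.ndarray, cs: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(arr, e, side="left")
        return e * idx - cs[idx]

    F = ramp_sum(edges, sa, csa) - ramp_sum(edges, sb, csb)
    return np.maximum(gene.basal_rate * dt * np.diff(F), 0.0)


def sample_reads(
    masses: Mapping[str, np.ndarray], reads_per_condition: int, seed
) -> dict[str, np.ndarray]:
    """Multinomially allocate a fixed read total across all bins of all genes
    in proportion to expected mass."""
    rng = np.random.default_rng(seed)
    gene_ids = list(masses)
    flat = np.concatenate([np.asarray(masses[g], dtype=float) for g in gene_ids])
    total = flat.sum()
    if total <= 0:
        warnings.warn("total expected mass is zero; emitting all-zero counts")
        counts = np.zeros(flat.size, dtype=float)
    else:
        counts = rng.multinomial(reads_per_condition, flat / total).astype(float)
    out: dict[str, np.ndarray] = {}
    i = 0
    for g in gene_ids:
        k = len(masses[g])
        out[g] = counts[i : i + k]
        i += k
    return out


@dataclass
class SimulationResult:
    gene_set: GeneSet
    config: SimulationConfig
    tracks: dict[Condition, dict[str, CoverageTrack]]
    rpkm: pd.DataFrame  # genes x condition labels
    library_size: float

    def conditions(self) -> list[Condition]:
        return list(self.tracks)

    def condition(self, dose: float, time_h: float, genotype: str) -> Condition:
        c = Condition(float(dose), float(time_h), genotype)
        if c not in self.tracks:
            raise KeyError(f"condition {c} not simulated")
        return c

    def control(self, genotype: str) -> Condition:
        return self.condition(0.0, 0.0, genotype)


def _empty_field(gene: Gene) -> LesionField:
    return LesionField(gene.id, np.array([]), np.array([]), density=0.0,
                       removal_assigned=True)


def simulate_experiment(gene_set: GeneSet, config: SimulationConfig) -> SimulationResult:
    """Run the full condition grid and return coverage tracks and RPKM.

    One lesion realization is drawn per (gene, dose) and shared across the
    timepoints and genotypes of that dose (paired design; removal times are
    re-drawn per genotype).  An unirradiated control (dose 0, t 0) is always
    included for every genotype.  The library size is calibrated once from
    the gene set so that control RPKM of a gene equals its basal rate on the
    conventional RPKM scale; all conditions share it, so UV redistributes a
    fixed read total across genes.
    """
    genes = list(gene_set)
    seed = config.seed

    mass_rate_bp = sum(g.basal_rate * g.length for g in genes)
    if mass_rate_bp <= 0:
        warnings.warn("gene set has no expressed genes")
        library_size = float(config.reads_per_condition)
    else:
        library_size = config.reads_per_condition * 1e9 / mass_rate_bp

    doses = tuple(sorted(set(config.doses) | {0.0}))
    fields: dict[tuple[int, int], LesionField] = {}
    for di, dose in enumerate(doses):
        dens = lesion_density(dose)
        for gi, gene in enumerate(genes):
            if dose == 0:
                fields[(gi, di)] = _empty_field(gene)
            else:
                fields[(gi, di)] = place_lesions(gene, dens, seed=[seed, 11, gi, di])

    tracks: dict[Condition, dict[str, CoverageTrack]] = {}
    rpkm_cols: dict[str, pd.Series] = {}
    lengths = np.array([g.length for g in genes], dtype=float)

    for gti, genotype in enumerate(config.genotypes):
        params = config.repair_params(genotype)
        for di, dose in enumerate(doses):
            times = (0.0,) if dose == 0 else config.timepoints
            assigned = []
            for gi, gene in enumerate(genes):
                f = fields[(gi, di)]
                if dose == 0:
                    assigned.append(f)
                else:
                    assigned.append(
                        assign_removal_times(f, gene, params, seed=[seed, 13, gi, di, gti])
                    )
            for ti, t in enumerate(times):
                cond = Condition(dose, t, genotype)
                masses = {
                    gene.id: simulate_bru_window(gene, assigned[gi], t, config)
                    for gi, gene in enumerate(genes)
                }
                counts = sample_reads(
                    masses, config.reads_per_condition, seed=[seed, 17, di, gti, ti]
                )
                tracks[cond] = {
                    gid: CoverageTrack(gid, config.bin_width, c, library_size, cond)
                    for gid, c in counts.items()
                }
                totals = np.array([counts[g.id].sum() for g in genes])
                rpkm_cols[cond.label] = pd.Series(
                    totals * 1e9 / (lengths * library_size), index=[g.id for g in genes]
                )
    rpkm = pd.DataFrame(rpkm_cols)
    rpkm.index.name = "gene_id"
    return SimulationResult(gene_set, config, tracks, rpkm, library_size)


def write_outputs(result: SimulationResult, outdir) -> Path:
    """Write one bedGraph and one RPKM TSV per condition plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for cond, trk in result.tracks.items():
        bg = outdir / f"coverage_{cond.label}.bedgraph"
        write_coverage(trk, result.gene_set, bg)
        tsv = outdir / f"rpkm_{cond.label}.tsv"
        write_rpkm_table(result.rpkm[cond.label], tsv)
        files[cond.label] = {"bedgraph": bg.name, "rpkm": tsv.name}
    cfg = asdict(result.config)
    manifest = {
        "config": cfg,
        "library_size": result.library_size,
        "gene_set_provenance": result.gene_set.provenance,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
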