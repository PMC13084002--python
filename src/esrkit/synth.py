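"""Seeded generators for every input class the analysis stages read, with
ground truth attached.

The generators emulate the study conditions: paired wild-type/mutant OD600
curves sampled every 15 min with a post-stress rate ratio of 0.9 and
multiplicative lognormal noise; acquired-resistance viability panels over 11
peroxide doses (0-20 mM) whose tolerated dose rises with NaCl pretreatment
time; 50:50 mixed-strain single-cell trace populations with an iRFP marker
channel and a post-T12 nuclear pulse; and clustered time-course fold-change
tables with mutant-specific defects, promoters carrying planted CCCCT /
GATGAG motifs, and biased TF-target sets.

Each generator draws from a single ``numpy.random.Generator`` stream seeded
from the config, so identical configs give identical outputs, and returns a
``truth`` dict describing the planted structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTable, GeneSetCollection, PromoterSeq
from .phenotypes import ODCurve, ViabilityPanel
from .traces import CellTrace


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # OD curves
    n_pairs: int = 100
    mutant_rate: float = 0.005  # per-minute post-stress rate (~140 min doubling)
    rate_ratio: float = 0.9  # wild-type / mutant post-stress rate ratio
    od_noise: float = 0.01  # multiplicative lognormal sigma
    od_start: float = 0.1
    lag_min: float = 0.0  # optional growth lag after stress addition
    t_max: float = 240.0
    sampling_min: float = 15.0
    # viability panels
    pretreat_times: tuple = (0, 10, 20, 30, 40, 50, 60, 90, 120)
    n_doses: int = 11
    max_dose: float = 20.0
    ld50_basal: float = 2.0  # mM tolerated with no pretreatment
    ld50_plateau: float = 14.0  # mM gained at full acquisition
    acquisition_tau: float = 30.0  # min; saturating-kinetics time constant
    acquisition_delay: float = 0.0  # min; delayed-acquisition strains
    protection_amplitude: float = 1.0  # 0 = no acquired protection
    dose_width: float = 1.0  # mM logistic steepness
    # cell traces
    n_cells: int = 200
    n_frames: int = 40
    stress_frame: int = 12  # pulse starts after this frame
    peak_height_wt: float = 1.0
    peak_deficit: float = 0.3  # mutant peak height = wt - deficit
    pulse_frames: int = 5
    baseline_nuclear: float = 1.0
    trace_noise: float = 0.02
    abundance_mean: float = 640.0
    abundance_sd: float = 15.0
    irfp_background: float = 100.0
    irfp_offset: float = 5.0  # marked-cell iRFP = offset x background
    # expression
    n_genes: int = 400
    n_timepoints: int = 4
    fc_amplitude: float = 2.0
    fc_noise: float = 0.15
    promoter_len: int = 500
    motif_density_target: float = 0.8  # planted-motif probability in its cluster
    motif_density_background: float = 0.1
    n_tfs: int = 30
    tf_target_frac: float = 0.1
    tf_bias_factor: float = 4.0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_cells", "n_genes", "n_doses", "n_frames"):
            if getattr(self, name) < 1:
                raise GeneratorError(f"{name} must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------


def gen_od_curves(cfg: GeneratorConfig) -> dict:
    """Paired wild-type / mutant post-stress OD600 curves.

    OD grows exponentially at the strain rate after an optional lag, with
    multiplicative lognormal noise; wild-type rate = ``rate_ratio`` x mutant
    rate (default 0.9, the fitted relative rate under 0.7 M NaCl).
    """
    rng = cfg.rng()
    times = np.arange(0.0, cfg.t_max + 1e-9, cfg.sampling_min)
    pairs = []
    r_mut = cfg.mutant_rate
    r_wt = cfg.rate_ratio * r_mut
    for i in range(cfg.n_pairs):
        curves = {}
        for strain, r in (("wt", r_wt), ("mutant", r_mut)):
            grown = np.clip(times - cfg.lag_min, 0.0, None)
            od = cfg.od_start * np.exp(r * grown)
            noise = np.exp(rng.normal(0.0, cfg.od_noise, size=times.size))
            curves[strain] = ODCurve(
                times=times, od=od * noise, strain=strain, replicate=f"rep{i}"
            )
        pairs.append(curves)
    truth = {"rate_wt": r_wt, "rate_mutant": r_mut, "rate_ratio": cfg.rate_ratio,
             "lag_min": cfg.lag_min, "seed": cfg.seed}
    return {"pairs": pairs, "truth": truth}


def gen_viability_panel(cfg: GeneratorConfig, strain: str = "wt") -> dict:
    """Dose-dependent survival rising with pretreatment time.

    Survival is logistic in peroxide dose around an LD50 that climbs from a
    basal value to a plateau with saturating kinetics in pretreatment time;
    ``acquisition_delay`` shifts the kinetics (the delayed-acquisition mutant
    phenotype) and ``protection_amplitude`` scales the gain (0 = a strain
    that never acquires resistance).
    """
    rng = cfg.rng()
    times = np.asarray(cfg.pretreat_times, dtype=float)
    doses = np.linspace(0.0, cfg.max_dose, cfg.n_doses)
    eff_t = np.clip(times - cfg.acquisition_delay, 0.0, None)
    ld50 = cfg.ld50_basal + cfg.protection_amplitude * cfg.ld50_plateau * (
        1.0 - np.exp(-eff_t / cfg.acquisition_tau)
    )
    surv = 1.0 / (1.0 + np.exp((doses[None, :] - ld50[:, None]) / cfg.dose_width))
    surv = np.clip(surv + rng.normal(0.0, 0.01, surv.shape), 0.0, 1.0)
    surv[:, 0] = 1.0  # no-peroxide reference
    panel = ViabilityPanel(
        pretreat_times=times, doses=doses, survival=surv, strain=strain
    )
    truth = {"ld50": ld50.tolist(), "delay_min": cfg.acquisition_delay,
             "amplitude": cfg.protection_amplitude, "seed": cfg.seed}
    return {"panel": panel, "truth": truth}


def gen_cell_traces(cfg: GeneratorConfig, with_patches: bool = False) -> dict:
    """Mixed 50:50 population of iRFP-marked wild-type and unmarked mutant
    cells with a post-stress nuclear pulse.

    Nuclear fraction sits near baseline with noise and jumps by the strain
    peak height for ``pulse_frames`` frames starting right after the stress
    frame; the mutant's pulse is smaller by ``peak_deficit``. Per-cell
    reporter abundance is lognormal around a shared mean so abundance-matched
    subsets exist; only marked cells carry the iRFP offset.
    """
    rng = cfg.rng()
    n_marked = cfg.n_cells // 2
    frames = np.arange(1, cfg.n_frames + 1)
    traces, patches = [], {}
    for i in range(cfg.n_cells):
        marked = i < n_marked
        strain = "wt_marked" if marked else "mutant"
        height = cfg.peak_height_wt - (0.0 if marked else cfg.peak_deficit)
        nf = cfg.baseline_nuclear + rng.normal(0.0, cfg.trace_noise, cfg.n_frames)
        start = cfg.stress_frame  # pulse spans frames T13..T13+pulse_frames-1
        nf[start : start + cfg.pulse_frames] += height
        abund = cfg.abundance_mean * math.exp(
            rng.normal(0.0, cfg.abundance_sd / cfg.abundance_mean)
        )
        ms = abund * np.exp(rng.normal(0.0, cfg.trace_noise, cfg.n_frames))
        irfp_level = cfg.irfp_background * (cfg.irfp_offset if marked else 1.0)
        irfp = irfp_level * np.exp(rng.normal(0.0, cfg.trace_noise, cfg.n_frames))
        tr = CellTrace(
            cell_id=f"cell{i:04d}",
            frames=frames,
            nuclear_fraction={"GFP": nf, "iRFP": np.ones(cfg.n_frames)},
            median_signal={"GFP": ms, "iRFP": irfp},
            strain_label=strain,
        )
        traces.append(tr)
        if with_patches:
            patches[tr.cell_id] = _patch_for(rng, nf[start], abund)
    truth = {
        "labels": [t.strain_label for t in traces],
        "peak_height": {"wt_marked": cfg.peak_height_wt,
                        "mutant": cfg.peak_height_wt - cfg.peak_deficit},
        "irfp_offset": cfg.irfp_offset,
        "seed": cfg.seed,
    }
    out = {"traces": traces, "truth": truth}
    if with_patches:
        out["patches"] = patches
    return out


def _patch_for(rng: np.random.Generator, target_ratio: float, level: float,
               n_pixels: int = 400) -> np.ndarray:
    """Pixel patch whose nc_ratio matches a target: 95% of pixels at the
    median level, the top 5% raised so top-mean / median = target."""
    n_top = max(1, math.ceil(0.05 * n_pixels))
    px = np.full(n_pixels, level, dtype=float)
    px[:n_top] = level * max(target_ratio, 1.0)
    rng.shuffle(px)
    return px


# ---------------------------------------------------------------------------


ARCHETYPES = ("induced", "induced_msn_defect", "repressed", "repressed_dot_defect")
STRAINS = ("wt", "msn2msn4", "dot6tod6")


def _archetype_fc(arch: str, strain: str, t_frac: np.ndarray, amp: float) -> np.ndarray:
    """Mean log2 fold-change time course for one archetype in one strain.

    Induced genes rise then relax; repressed genes mirror them. Defect
    variants halve the response in the corresponding mutant.
    """
    shape = 4.0 * t_frac * (1.0 - 0.5 * t_frac)  # fast rise, slow relaxation
    shape = shape / shape.max()
    base = amp * shape
    if arch.startswith("repressed"):
        base = -base
    scale = 1.0
    if arch == "induced_msn_defect" and strain == "msn2msn4":
        scale = 0.35
    if arch == "repressed_dot_defect" and strain == "dot6tod6":
        scale = 0.35
    return scale * base


def gen_expression(cfg: GeneratorConfig) -> dict:
    """Fold-change table + promoters + TF-target sets with planted truth.

    Genes split evenly over four temporal archetypes (induced, induced with
    an Msn2/4-dependent defect, repressed, repressed with a Dot6/Tod6-
    dependent defect). FDR columns for each mutant contrast are small where
    the mutant deviates from wild-type and near 1 elsewhere. Promoters carry
    the STRE pentamer (CCCCT) at high density upstream of the Msn2/4-
    dependent induced cluster and the PAC-type GATGAG upstream of the
    Dot6/Tod6-dependent repressed cluster. One TF-target set per planted
    regulator is biased toward its cluster.
    """
    rng = cfg.rng()
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    arch = np.array([ARCHETYPES[i % len(ARCHETYPES)] for i in range(cfg.n_genes)])
    t_frac = np.linspace(0.25, 1.0, cfg.n_timepoints)
    timepoints = list(range(1, cfg.n_timepoints + 1))

    rows = []
    for strain in STRAINS:
        for gi, g in enumerate(genes):
            mean = _archetype_fc(arch[gi], strain, t_frac, cfg.fc_amplitude)
            fc = mean + rng.normal(0.0, cfg.fc_noise, cfg.n_timepoints)
            defective = (
                (strain == "msn2msn4" and arch[gi] == "induced_msn_defect")
                or (strain == "dot6tod6" and arch[gi] == "repressed_dot_defect")
            )
            if strain == "wt":
                fdr = [np.nan] * cfg.n_timepoints
            else:
                fdr = np.where(
                    defective,
                    rng.uniform(1e-6, 0.01, cfg.n_timepoints),
                    rng.uniform(0.2, 1.0, cfg.n_timepoints),
                )
            for ti, tp in enumerate(timepoints):
                rows.append(
                    {"gene": g, "strain": strain, "timepoint": tp,
                     "log2fc": fc[ti], "fdr": fdr[ti]}
                )
    table = ExpressionTable(pd.DataFrame(rows))

    # promoters with planted motifs
    motif_for = {"induced_msn_defect": "CCCCT", "repressed_dot_defect": "GATGAG"}
    promoters = []
    for gi, g in enumerate(genes):
        seq = rng.choice(list("ACGT"), size=cfg.promoter_len)
        for motif, owner in (("CCCCT", "induced_msn_defect"),
                             ("GATGAG", "repressed_dot_defect")):
            dens = (
                cfg.motif_density_target
                if arch[gi] == owner
                else cfg.motif_density_background
            )
            if rng.random() < dens:
                pos = int(rng.integers(0, cfg.promoter_len - len(motif)))
                seq[pos : pos + len(motif)] = list(motif)
        promoters.append(PromoterSeq(gene=g, sequence="".join(seq)))

    # TF-target sets; two planted regulators biased to their clusters
    universe = set(genes)
    sets: dict[str, set[str]] = {}
    n_targets = max(3, int(cfg.tf_target_frac * cfg.n_genes))
    for t in range(cfg.n_tfs):
        sets[f"TF{t:02d}"] = set(rng.choice(genes, size=n_targets, replace=False))
    for tf_name, owner in (("MSN2_4", "induced_msn_defect"),
                           ("DOT6_TOD6", "repressed_dot_defect")):
        in_cluster = [g for gi, g in enumerate(genes) if arch[gi] == owner]
        out_cluster = [g for gi, g in enumerate(genes) if arch[gi] != owner]
        n_in = min(len(in_cluster), int(0.75 * n_targets * cfg.tf_bias_factor / 4.0) * 4)
        n_in = max(n_in, n_targets // 2)
        chosen = set(rng.choice(in_cluster, size=min(n_in, len(in_cluster)), replace=False))
        chosen |= set(rng.choice(out_cluster, size=n_targets // 4, replace=False))
        sets[tf_name] = chosen
    collection = GeneSetCollection(sets=sets, universe=universe)

    truth = {
        "archetype": dict(zip(genes, arch.tolist())),
        "motif_for": motif_for,
        "planted_tfs": {"MSN2_4": "induced_msn_defect",
                        "DOT6_TOD6": "repressed_dot_defect"},
        "seed": cfg.seed,
    }
    return {
        "table": table,
        "promoters": promoters,
        "tf_targets": collection,
        "truth": truth,
    }
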