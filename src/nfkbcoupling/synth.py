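"""Synthetic-data generators emulating the study's data structures.

These stand in for the raw measurements (which were not deposited): a
50-gene qPCR time course in EMT (+TGFβ) and control (−TGFβ) states with
planted cluster structure and missing cells, noisy p52 trajectories for
the delay-recovery experiments, and genomic-DNA dilution series for
standard-curve fitting. All generators are pure functions of their plan
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import StimulusProgram, simulate
from .params import ModelParameters
from .qpcr import DEFAULT_REFERENCE_GENE, CtTable, load_panel

#: Stimulation time points, hours (figures span 1-24 h plus baseline).
DEFAULT_TIME_POINTS_H = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)

CONDITIONS = ("EMT", "control")

#: Cluster archetypes: per-time multiplier shapes on the log2 scale.
_PROFILES = {
    # canonical NF-κB / growth-factor response genes: up in both states,
    # markedly amplified by EMT, early onset
    "nfkb_up": {"control": (0, 1.5, 2.0, 1.5, 1.0, 0.5),
                "EMT": (0, 3.0, 3.8, 3.4, 2.8, 2.0)},
    # TRAF1-like: peaks at 12 h, ~20-fold in EMT vs ~3-fold in control
    "traf1_like": {"control": (0, 0.6, 1.0, 1.4, 1.6, 1.2),
                   "EMT": (0, 1.5, 2.5, 3.5, 4.3, 3.8)},
    # interferon/ISG cluster: induced in control, shut down under EMT
    "ifn_down": {"control": (0, 1.0, 2.0, 2.5, 2.0, 1.5),
                 "EMT": (0, -1.0, -2.0, -2.5, -3.0, -3.0)},
    # mesenchymal program: constitutively up in the EMT state
    "emt_program_up": {"control": (0, 0.0, 0.2, 0.2, 0.3, 0.3),
                       "EMT": (2.5, 2.8, 3.0, 3.2, 3.4, 3.5)},
    # housekeeping-like background
    "flat": {"control": (0, 0.1, 0.1, 0.0, -0.1, 0.0),
             "EMT": (0, 0.0, 0.2, 0.1, 0.0, -0.1)},
}

_PATHWAY_CLUSTER = {
    "canonical": "nfkb_up",
    "noncanonical_emt": "emt_program_up",
    "ifn": "ifn_down",
    "growth_factor": "nfkb_up",
    "ros_dna": "flat",
    "cell_cycle": "flat",
}


@dataclass
class GeneratorPlan:
    """Planned structure of a synthetic Ct time course."""

    panel: pd.DataFrame
    fold_change: pd.DataFrame  # genes x (condition, time_h) planned fold changes
    cluster_of: dict[str, str]
    noise_sd_ct: float = 0.25
    missing_rate: float = 0.04
    seed: int = 0
    reference_gene: str = DEFAULT_REFERENCE_GENE
    reference_ct: float = 20.0
    gene_baseline_ct: float = 26.0
    n_replicates: int = 3
    time_points_h: tuple = DEFAULT_TIME_POINTS_H

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.noise_sd_ct < 0:
            raise ValueError("noise_sd_ct must be >= 0")
        if (self.fold_change <= 0).any().any():
            raise ValueError("planned fold changes must be > 0")


def default_plan(seed: int = 0, noise_sd_ct: float = 0.25,
                 missing_rate: float = 0.04,
                 time_points_h=DEFAULT_TIME_POINTS_H) -> GeneratorPlan:
    """Plan echoing the study's qualitative structure.

    Interferon genes are shut down by EMT, NF-κB/growth-factor genes are
    amplified (TRAF1 peaking at 12 h with ~20-fold EMT vs ~3-fold control
    induction), and the mesenchymal program is constitutively up in the
    EMT state.
    """
    panel = load_panel()
    genes = list(panel.gene)
    cluster_of = {
        g: _PATHWAY_CLUSTER[p] for g, p in zip(panel.gene, panel.pathway)
    }
    cluster_of["TRAF1"] = "traf1_like"
    cluster_of["NFKB2"] = "traf1_like"
    cluster_of["TNIP1"] = "traf1_like"
    cols = pd.MultiIndex.from_product(
        [CONDITIONS, time_points_h], names=["condition", "time_h"]
    )
    rows = []
    for g in genes:
        prof = _PROFILES[cluster_of[g]]
        log2fc = [prof[c][i] for c in CONDITIONS
                  for i in range(len(time_points_h))]
        rows.append(np.power(2.0, log2fc))
    fc = pd.DataFrame(rows, index=genes, columns=cols)
    return GeneratorPlan(panel, fc, cluster_of, noise_sd_ct, missing_rate, seed,
                         time_points_h=tuple(time_points_h))


def gen_ct_timecourse(plan: GeneratorPlan) -> CtTable:
    """Emit a long-format Ct table realising the planned fold changes.

    Cts are constructed by the inverse of the comparative-Ct formula
    (Ct = Ct_ref + ΔCt_control − log2 fold-change) so that at zero noise
    the ΔΔCt pipeline recovers the planned matrix exactly. Additive
    Gaussian noise (the natural scale of qPCR error) and missing cells
    are injected from the seeded generator; metadata (the seed) rides in
    the replicate labels' run tag.
    """
    rng = np.random.default_rng(plan.seed)
    genes = list(plan.fold_change.index)
    records = []
    # per-gene constant offset from the reference assay in the control column
    base_dct = {g: plan.gene_baseline_ct - plan.reference_ct for g in genes}
    for cond in CONDITIONS:
        for t_h in plan.time_points_h:
            t_min = 60.0 * t_h
            for rep in range(1, plan.n_replicates + 1):
                ct_ref = plan.reference_ct + rng.normal(0, plan.noise_sd_ct)
                records.append(
                    (plan.reference_gene, "reference", cond, t_min, rep, ct_ref)
                )
            for g in genes:
                fc = plan.fold_change.loc[g, (cond, t_h)]
                ct_clean = plan.reference_ct + base_dct[g] - np.log2(fc)
                if not 0 < ct_clean <= 40:
                    raise ValueError(
                        f"plan implies Ct {ct_clean:.2f} outside (0, 40] "
                        f"for gene {g}"
                    )
                pathway = plan.panel.loc[plan.panel.gene == g, "pathway"].iloc[0]
                for rep in range(1, plan.n_replicates + 1):
                    ct = ct_clean + rng.normal(0, plan.noise_sd_ct) \
                        if plan.noise_sd_ct > 0 else ct_clean
                    if rng.random() < plan.missing_rate:
                        ct = np.nan
                    records.append((g, pathway, cond, t_min, rep, ct))
    df = pd.DataFrame(
        records,
        columns=["gene", "pathway", "condition", "time_min", "replicate", "ct"],
    )
    df["replicate"] = df["replicate"].map(lambda r: f"s{plan.seed}_r{r}")
    return CtTable(df)


def gen_noisy_trajectories(
    params: ModelParameters,
    true_delays: tuple[float, float],
    noise_sd_fraction: float,
    seed: int,
    t_end_min: float = 600.0,
    dt_out_min: float = 1.0,
):
    """p52 series simulated at known delays with multiplicative noise.

    Returns ``(times_min, p52_noisy, p52_clean)``; each output sample is
    multiplied by an independent ``1 + sd * N(0, 1)`` factor (clipped at
    zero), seeded for reproducibility.
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    tau1, tau2 = true_delays
    p = params.replace(tau_traf1_min=tau1, tau_nfkb2_min=tau2)
    traj = simulate(p, StimulusProgram(), t_end_min, dt_out_min)
    clean = traj.value("p52").copy()
    rng = np.random.default_rng(seed)
    noisy = clean * np.clip(1.0 + noise_sd_fraction * rng.standard_normal(clean.size), 0.0, None)
    return traj.times_min.copy(), noisy, clean


def gen_dilution_series(true_slope: float, true_intercept: float,
                        masses_ng, noise_sd: float, seed: int):
    """Dilution series (mass, Ct) from a known line plus seeded noise."""
    masses = np.asarray(list(masses_ng), dtype=float)
    if masses.size == 0:
        raise ValueError("empty mass list")
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0 ng")
    rng = np.random.default_rng(seed)
    cts = true_slope * np.log10(masses) + true_intercept
    if noise_sd > 0:
        cts = cts + rng.normal(0, noise_sd, size=masses.size)
    return list(zip(masses.tolist(), cts.tolist()))
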