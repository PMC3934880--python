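"""Synthetic experiments with known global mRNA-content shifts.

The generator emulates the early-embryo polyA+ dynamics that motivate
biological scaling: a per-embryo pool of transcript abundances T_ij whose
*total* C_j = Σ_i T_ij drifts across developmental stages, sequenced to a
depth D_j that is independent of C_j. Reads are allocated by relative
abundance, μ_ij = D_j · T_ij / C_j, which is precisely the mechanism that
erases global shifts from raw counts — the simulator makes every
normalization method's bias measurable against stored ground truth.

Scenarios
---------
``pre_zga_polyadenylation``
    Cytoplasmic polyadenylation before zygotic genome activation: a large
    fraction of maternal transcripts (default 70%) ramps *into* the polyA+
    pool between the 1-cell stage and 3.5 hpf, raising total content to a
    target of ≈1.55× (the measured 1.5–1.7× band).
``post_zga_decay``
    miR-430–driven clearance after activation: a fraction of transcripts
    decays between 3.5 and 5.3 hpf, dropping content to ≈0.65×.
``custom``
    Caller-specified fraction, content target and stage progress.

Per-gene shift magnitudes are log-normal around the scenario target; the
*realized* content scales (recomputed by summing the emitted abundances)
are stored as truth, not the nominal target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .qpcr import QpcrTable
from .scaling import ScaleSet

__all__ = ["SimConfig", "SimTruth", "simulate_truth", "simulate_counts", "simulate_qpcr"]

SCENARIOS = ("pre_zga_polyadenylation", "post_zga_decay", "custom")

_SCENARIO_STAGES = {
    "pre_zga_polyadenylation": ("1-cell", "16-cell", "128-cell", "3.5hpf"),
    "post_zga_decay": ("3.5hpf", "5.3hpf"),
}
_SCENARIO_CONTENT = {
    "pre_zga_polyadenylation": 1.55,  # within the measured 1.5-1.7x rise
    "post_zga_decay": 0.65,  # within the measured 0.6-0.7x fall
}


@dataclass
class SimConfig:
    """Knobs for one synthetic experiment.

    ``fraction_shifted`` (f) is the proportion of genes that change;
    ``content_ratio`` the target C_final/C_ref at full progress;
    ``shift_log_sd`` the sd of log shift magnitudes (0 gives a uniform
    shift); ``progress`` the per-stage fraction of the full shift applied
    (defaults: linear ramp for the pre-ZGA scenario, a single step for the
    post-ZGA one); ``dispersion`` the negative-binomial φ in
    var = μ + φμ²; ``depth`` the per-sample sequencing depth with optional
    log-normal jitter (independent of content by construction).
    """

    n_genes: int = 5000
    scenario: str = "pre_zga_polyadenylation"
    stages: tuple[str, ...] | None = None
    fraction_shifted: float = 0.7
    content_ratio: float | None = None
    shift_log_sd: float = 0.25
    progress: tuple[float, ...] | None = None
    depth: float = 5e6
    depth_jitter_sd: float = 0.0
    dispersion: float = 0.1
    abundance_log_mean: float = 4.0
    abundance_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.fraction_shifted <= 1.0:
            raise ValueError("fraction_shifted must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.stages is None:
            if self.scenario == "custom":
                raise ValueError("custom scenario requires explicit stages")
            self.stages = _SCENARIO_STAGES[self.scenario]
        self.stages = tuple(self.stages)
        if self.content_ratio is None:
            if self.scenario == "custom":
                raise ValueError("custom scenario requires a content_ratio")
            self.content_ratio = _SCENARIO_CONTENT[self.scenario]
        if self.content_ratio <= 1.0 - self.fraction_shifted and self.fraction_shifted > 0:
            raise ValueError(
                "content_ratio unreachable: even total loss of the shifted "
                f"fraction cannot go below {1.0 - self.fraction_shifted}"
            )
        if self.progress is None:
            k = len(self.stages)
            if self.scenario == "post_zga_decay":
                self.progress = tuple(0.0 if i < k - 1 else 1.0 for i in range(k))
            else:
                self.progress = tuple(i / (k - 1) if k > 1 else 0.0 for i in range(k))
        self.progress = tuple(float(p) for p in self.progress)
        if len(self.progress) != len(self.stages):
            raise ValueError("progress must have one entry per stage")
        if self.progress[0] != 0.0:
            raise ValueError("the first stage is the reference; progress[0] must be 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``abundances`` holds per-embryo transcript abundances T_ij (arbitrary
    molecule units) for genes × stages; everything else is derived from it
    or copied from the config. The first stage is the reference.
    """

    abundances: pd.DataFrame
    depths: pd.Series
    dispersion: float
    shifted_genes: list[str]
    config: SimConfig = field(repr=False)

    @property
    def stages(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def reference_stage(self) -> str:
        return self.abundances.columns[0]

    @property
    def content_totals(self) -> pd.Series:
        """C_j = Σ_i T_ij."""
        return self.abundances.sum(axis=0)

    @property
    def scales(self) -> ScaleSet:
        """True global scales Z_j = C_j / C_ref (realized, not nominal)."""
        c = self.content_totals
        z = (c / c.iloc[0]).to_numpy()
        z[0] = 1.0
        return ScaleSet(
            sample_ids=self.stages,
            scales=z,
            kind="user",
            reference=self.reference_stage,
            convention="relative-to-reference",
            provenance=["simulation ground truth"],
        )

    def log2_fold_changes(self, numerator: str, denominator: str) -> pd.Series:
        """True per-gene log2(T_num / T_den)."""
        t = self.abundances
        return np.log2(t[numerator] / t[denominator]).rename("log2_fc")


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-embryo transcript abundances for every stage.

    Baseline abundances at the reference stage are log-normal; a seeded
    random subset of round(f·n_genes) genes receives a multiplicative shift
    m_i (log-normal, mean chosen so the expected content ratio at full
    progress hits the configured target), applied per stage as m_i^progress.
    Deterministic given the config (seed included).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    base = rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd, cfg.n_genes)

    n_shift = int(round(cfg.fraction_shifted * cfg.n_genes))
    if cfg.fraction_shifted > 0 and n_shift < 1:
        warnings.warn(
            "fraction_shifted rounds to zero shifted genes", UserWarning, stacklevel=2
        )
    shifted_idx = np.sort(rng.choice(cfg.n_genes, size=n_shift, replace=False))

    mult = np.ones(cfg.n_genes)
    if n_shift > 0:
        f = n_shift / cfg.n_genes
        mean_mult = (cfg.content_ratio - (1.0 - f)) / f
        mu = np.log(mean_mult) - 0.5 * cfg.shift_log_sd**2
        mult[shifted_idx] = rng.lognormal(mu, cfg.shift_log_sd, n_shift)

    cols = {}
    for stage, p in zip(cfg.stages, cfg.progress):
        cols[stage] = base * mult**p
    abund = pd.DataFrame(cols, index=genes)

    if cfg.depth_jitter_sd > 0:
        depths = cfg.depth * rng.lognormal(0.0, cfg.depth_jitter_sd, len(cfg.stages))
    else:
        depths = np.full(len(cfg.stages), cfg.depth, dtype=float)
    return SimTruth(
        abundances=abund,
        depths=pd.Series(depths, index=list(cfg.stages), name="depth"),
        dispersion=cfg.dispersion,
        shifted_genes=[genes[i] for i in shifted_idx],
        config=cfg,
    )


def simulate_counts(
    truth: SimTruth, seed: int, n_replicates: int = 1
) -> CountMatrix:
    """Sequence the simulated pools: NB counts with depth-decoupled means.

    μ_ij = D_j · T_ij / C_j, so expected column totals equal the depths
    regardless of content — raw counts carry no trace of the global shift.
    φ > 0 gives negative-binomial counts (gamma–Poisson mixture with
    var = μ + φμ²); φ = 0 is pure Poisson. With ``n_replicates`` > 1 the
    samples are named ``stage:rK`` and the stage map is available as the
    returned matrix's ``groups`` attribute.
    """
    rng = np.random.default_rng(seed)
    c = truth.content_totals
    cols, groups = {}, {}
    for stage in truth.stages:
        mu = truth.depths[stage] * truth.abundances[stage].to_numpy() / c[stage]
        for r in range(n_replicates):
            name = stage if n_replicates == 1 else f"{stage}:r{r + 1}"
            if truth.dispersion > 0:
                shape = 1.0 / truth.dispersion
                lam = rng.gamma(shape, mu / shape)
                cols[name] = rng.poisson(lam)
            else:
                cols[name] = rng.poisson(mu)
            groups[name] = stage
    cm = CountMatrix(pd.DataFrame(cols, index=truth.abundances.index))
    cm.groups = groups
    return cm


def simulate_qpcr(
    truth: SimTruth,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    genes: list[str] | None = None,
    n_replicates: int = 3,
    ct_intercept: float = 35.0,
    reference_ct: float = 15.0,
) -> QpcrTable:
    """Matched synthetic qPCR: Ct from per-embryo abundances plus a spike-in.

    Target Ct = ct_intercept − log_E(T_ij) + N(0, ct_noise_sd); the
    spike-in reference ("kanamycin", a fixed amount per embryo pool) has a
    constant Ct across stages plus the same noise. Because T is per-embryo,
    noise-free tables invert exactly to the true fold changes. The primer
    efficiency used to *generate* is also recorded in the table for both
    target and reference primers; analysing with an assumed E = 2 when
    generation used E < 2 reproduces the classic ΔΔCt bias.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    rng = np.random.default_rng(seed)
    if genes is None:
        k = min(20, truth.abundances.shape[0])
        genes = sorted(rng.choice(truth.abundances.index, size=k, replace=False))
    log_e = np.log(efficiency)
    rows = []
    for stage in truth.stages:
        for rep in range(1, n_replicates + 1):
            for g in genes:
                t = truth.abundances.at[g, stage]
                ct = ct_intercept - np.log(t) / log_e + rng.normal(0.0, ct_noise_sd)
                rows.append({"gene": g, "stage": stage, "replicate": f"r{rep}", "ct": ct})
            rows.append(
                {
                    "gene": "kanamycin",
                    "stage": stage,
                    "replicate": f"r{rep}",
                    "ct": reference_ct + rng.normal(0.0, ct_noise_sd),
                }
            )
    eff = {g: efficiency for g in genes}
    eff["kanamycin"] = efficiency
    return QpcrTable(pd.DataFrame(rows), reference_gene="kanamycin", efficiencies=eff)


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a config (for YAML round-trips)."""
    d = asdict(config)
    d["stages"] = list(d["stages"])
    d["progress"] = list(d["progress"])
    return d
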