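"""Synthetic study generator with known ground truth.

Emulates a bidirectional transwell screen of ~83 compounds across four MDR1
ortholog cell lines (human, rat, mouse, cynomolgus monkey), a mock control
and a human BCRP line, together with in vivo K_p,uu,brain values generated
from the scaled-efflux model, raw well-level measurements, transporter
abundance tables and seven-point inhibitor dose-response series.

Design notes
------------
* Efflux ratios are lognormal above a passive floor of 1: per-compound latent
  log net-ERs are drawn from a multivariate normal whose cross-ortholog
  correlations and per-line scales are calibrated to the published
  inter-ortholog R^2 values and per-line interquartile ranges.
* Compound archetypes: efflux substrates (MDR1 and/or BCRP), non-substrates,
  low-passive-permeability mimics (restricted in vivo without efflux) and
  uptake mimics (K_p,uu > 1.2 despite efflux).  Substrate archetypes are
  drawn so that the efflux burden alone restricts penetration
  (alpha*NET_MDR1 + beta*NET_BCRP >= margin); weak draws are rescaled up to
  the margin, so in the noise-free limit the in vitro substrate call and the
  in vivo restriction agree exactly.
* Every random quantity flows from one integer seed through per-stage
  `numpy` SeedSequences, so a fixed seed yields byte-identical outputs no
  matter which generator entry point is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .ic50 import DoseResponseSeries, four_param_logistic
from .kpuu import predict_kpuu_scaled

__all__ = [
    "GeneratorConfig",
    "IC50Truth",
    "SimulatedStudy",
    "generate_efflux_panel",
    "generate_invivo_kpuu",
    "generate_wells",
    "generate_abundance",
    "generate_dose_response",
    "simulate_study",
]

MDR1_LINES = ("hMDR1", "rMDR1", "mMDR1", "cyMDR1")

#: Published inter-ortholog R^2 of the 83-compound ER panels, used as
#: correlation targets for the latent log-ER draws.
DEFAULT_R2 = {
    ("hMDR1", "rMDR1"): 0.88,
    ("hMDR1", "mMDR1"): 0.87,
    ("hMDR1", "cyMDR1"): 0.76,
    ("rMDR1", "mMDR1"): 0.97,
    ("rMDR1", "cyMDR1"): 0.88,
    ("mMDR1", "cyMDR1"): 0.91,
}

#: Published per-line ER interquartile ranges used as dispersion targets.
DEFAULT_IQR = {"hMDR1": 16.57, "rMDR1": 8.92, "mMDR1": 8.09, "cyMDR1": 4.85}

#: Log-scale spread of the substrate net-ER distribution per line; the wider
#: human spread reflects its larger dynamic range.
DEFAULT_LOG_SIGMA = {"hMDR1": 1.2, "rMDR1": 1.1, "mMDR1": 1.1, "cyMDR1": 1.0}

#: Transporter abundances (pmol/mg membrane protein): overexpressing cell
#: lines and brain microvessels, representative of targeted-proteomics
#: magnitudes (cells tens of pmol/mg, microvessels a few pmol/mg).
DEFAULT_ABUNDANCE = {
    "hMDR1": (42.0, 4.2),
    "rMDR1": (30.0, 4.2),
    "mMDR1": (28.0, 4.2),
    "cyMDR1": (21.0, 4.2),
    "BCRP": (30.0, 4.4),
}


@dataclass(frozen=True)
class IC50Truth:
    """Ground truth for one inhibitor: per-line IC50s (uM) or censored."""

    inhibitor_id: str
    ic50_by_line: dict
    hill: float = 1.0
    censored: bool = False
    #: multiplier applied to the IC50 when quinidine replaces digoxin
    quinidine_shift: float = 0.5


def _default_ic50_truths() -> tuple:
    return (
        IC50Truth("zosuquidar-like", {l: 0.05 for l in MDR1_LINES}, hill=1.2),
        IC50Truth("ketoconazole-like", {l: 5.0 for l in MDR1_LINES}, hill=1.0),
        # abundance-proportional potency (IC50 scales with cell abundance)
        IC50Truth(
            "csa-like",
            {l: 0.5 * DEFAULT_ABUNDANCE[l][0] for l in MDR1_LINES},
            hill=0.8,
        ),
        IC50Truth(
            "verapamil-like",
            {"hMDR1": 30.0, "rMDR1": 1.5, "mMDR1": 2.0, "cyMDR1": 1.0},
            hill=1.0,
        ),
        IC50Truth("ritonavir-like", {l: float("nan") for l in MDR1_LINES}, censored=True),
        IC50Truth("talinolol-like", {l: float("nan") for l in MDR1_LINES}, censored=True),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic screen.

    Defaults reproduce the screen's design: 83 compounds, 47 of them MDR1
    substrates, four MDR1 ortholog lines plus mock and BCRP, six replicate
    wells per mean, 1 uM dosing sampled at 120 min, in vivo K_p,uu for a
    58-compound subset generated from the scaled-efflux model with
    alpha=0.52, beta=0.29 under multiplicative lognormal noise (sigma=0.3),
    with three low-permeability mimics and four uptake mimics exercising the
    exclusion paths.
    """

    n_compounds: int = 83
    seed: int = 0
    alpha_true: float = 0.52
    beta_true: float = 0.29
    kpuu_noise_sigma: float = 0.3
    n_kpuu_compounds: int = 58
    frac_mdr1_substrate: float = 47.0 / 83.0
    frac_bcrp_substrate: float = 0.15
    n_low_permeability: int = 3
    n_uptake: int = 4
    restriction_margin: float = 2.4
    er_iqr_targets: dict = field(default_factory=lambda: dict(DEFAULT_IQR))
    er_log_sigma: dict = field(default_factory=lambda: dict(DEFAULT_LOG_SIGMA))
    inter_ortholog_r2: dict = field(default_factory=lambda: dict(DEFAULT_R2))
    bcrp_log_mu: float = 1.6
    bcrp_log_sigma: float = 0.8
    nonsub_log_sigma: float = 0.08
    mock_log_sigma: float = 0.05
    # well-level assay structure
    cv_well: float = 0.12
    recovery_loss_range: tuple = (0.0, 0.25)
    n_low_recovery: int = 2
    ly_fail_rate: float = 0.02
    replicates: int = 6
    c0_donor_uM: float = 1.0
    t_end_min: float = 120.0
    filter_area_cm2: float = 0.11
    donor_volume_mL: float = 0.25
    receiver_volume_mL: float = 0.25
    papp_passive_median: float = 8e-6
    papp_passive_log_sigma: float = 0.4
    papp_low_perm: float = 3e-7
    # dose-response structure
    ic50_truths: tuple = field(default_factory=_default_ic50_truths)
    dr_noise_sd_pct: float = 3.0
    dr_n_concentrations: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.ly_fail_rate <= 1):
            raise InvalidInputError("ly_fail_rate must be in [0, 1]")
        if not (0 <= self.frac_mdr1_substrate <= 1 and 0 <= self.frac_bcrp_substrate <= 1):
            raise InvalidInputError("substrate fractions must be in [0, 1]")
        if self.kpuu_noise_sigma < 0 or self.cv_well < 0:
            raise InvalidInputError("noise parameters must be >= 0")

    def noise_free(self) -> "GeneratorConfig":
        """Copy of the config with every noise source and QC failure off.

        The misclassified-by-construction archetypes (low-permeability and
        uptake mimics) are also removed, so noise-free data are perfectly
        classifiable and parameter recovery is exact.
        """
        return replace(
            self,
            kpuu_noise_sigma=0.0,
            cv_well=0.0,
            recovery_loss_range=(0.0, 0.0),
            n_low_recovery=0,
            ly_fail_rate=0.0,
            n_low_permeability=0,
            n_uptake=0,
            dr_noise_sd_pct=0.0,
        )


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    corr = np.eye(len(MDR1_LINES))
    for i, a in enumerate(MDR1_LINES):
        for j, b in enumerate(MDR1_LINES):
            if i < j:
                r2 = config.inter_ortholog_r2.get((a, b), config.inter_ortholog_r2.get((b, a)))
                if r2 is None:
                    raise InvalidInputError(f"missing correlation target for {a}/{b}")
                corr[i, j] = corr[j, i] = np.sqrt(r2)
    # allow the singular perfectly-correlated limit; reject true infeasibility
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise InvalidInputError("inter-ortholog correlation matrix is not positive semidefinite")
    return corr


def _calibrate_log_mu(config: GeneratorConfig) -> dict:
    """Solve the latent location per line so the panel IQR hits its target.

    With non-substrates clustered at ER ~= 1 and a substrate fraction p >
    0.25, Q1 sits in the non-substrate cluster (~1) and Q3 at the
    within-substrate quantile q* = 1 - 0.25/p of the lognormal net-ER, so
    IQR ~= exp(mu + z(q*) sigma), giving mu in closed form.
    """
    p = config.frac_mdr1_substrate
    if p <= 0.25:
        raise InvalidInputError("IQR calibration requires a substrate fraction > 0.25")
    zq = stats.norm.ppf(1.0 - 0.25 / p)
    return {
        line: np.log(config.er_iqr_targets[line]) - zq * config.er_log_sigma[line]
        for line in MDR1_LINES
    }


def generate_efflux_panel(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Compound x cell-line ER panel with latent ground truth.

    Returns a DataFrame with one row per compound (archetype, substrate
    flags, per-line vehicle/inhibited ERs and NET ERs) and a truth record
    holding the latent values and generator parameters.
    """
    rng = _stage_rng(config.seed, 0)
    n = config.n_compounds
    n_sub = int(round(config.frac_mdr1_substrate * n))

    # archetype assignment; mimic archetypes live inside the in-vivo subset
    archetype = np.array(["non_substrate"] * n, dtype=object)
    mdr1_sub = np.zeros(n, dtype=bool)
    order = rng.permutation(n)
    sub_idx = order[:n_sub]
    mdr1_sub[sub_idx] = True
    archetype[sub_idx] = "mdr1_substrate"

    in_vivo_pool = np.arange(min(config.n_kpuu_compounds, n))
    up_pool = [i for i in in_vivo_pool if mdr1_sub[i]]
    lp_pool = [i for i in in_vivo_pool if not mdr1_sub[i]]
    uptake_idx = np.array(up_pool[: config.n_uptake], dtype=int)
    lowperm_idx = np.array(lp_pool[: config.n_low_permeability], dtype=int)
    archetype[uptake_idx] = "uptake_mimic"
    archetype[lowperm_idx] = "low_permeability"

    bcrp_sub = rng.random(n) < config.frac_bcrp_substrate
    bcrp_sub[lowperm_idx] = False

    # latent correlated log net-ERs for the MDR1 orthologs
    corr = _correlation_matrix(config)
    z = rng.multivariate_normal(np.zeros(len(MDR1_LINES)), corr, size=n, method="svd")
    log_mu = _calibrate_log_mu(config)
    net = {}
    for j, line in enumerate(MDR1_LINES):
        lat = np.exp(log_mu[line] + config.er_log_sigma[line] * z[:, j])
        non = np.maximum(np.exp(rng.normal(0.0, config.nonsub_log_sigma, n)) - 1.0, 0.0)
        net[line] = np.where(mdr1_sub, lat, non)
    net_bcrp = np.where(
        bcrp_sub,
        np.exp(rng.normal(config.bcrp_log_mu, config.bcrp_log_sigma, n)),
        np.maximum(np.exp(rng.normal(0.0, config.nonsub_log_sigma, n)) - 1.0, 0.0),
    )

    # enforce the restriction margin for efflux-substrate archetypes: weak
    # joint draws are rescaled so efflux alone explains brain restriction
    burden = config.alpha_true * net["hMDR1"] + config.beta_true * net_bcrp
    is_efflux_sub = mdr1_sub | bcrp_sub
    weak = is_efflux_sub & (burden < config.restriction_margin)
    factor = np.ones(n)
    factor[weak] = config.restriction_margin / burden[weak]
    for line in MDR1_LINES:
        net[line] = net[line] * factor
    net_bcrp = net_bcrp * factor

    mock_er = np.exp(rng.normal(0.0, config.mock_log_sigma, n))

    compounds = [f"CPD{i:03d}" for i in range(n)]
    df = pd.DataFrame({"compound_id": compounds, "archetype": archetype})
    df["mdr1_substrate"] = mdr1_sub
    df["bcrp_substrate"] = bcrp_sub
    for line in MDR1_LINES:
        df[f"er_{line}"] = 1.0 + net[line]
        df[f"net_er_{line}"] = net[line]
    df["er_hBCRP"] = 1.0 + net_bcrp
    df["net_er_hBCRP"] = net_bcrp
    df["er_mock"] = mock_er

    truth = {
        "alpha_true": config.alpha_true,
        "beta_true": config.beta_true,
        "log_mu": {k: float(v) for k, v in log_mu.items()},
        "n_mdr1_substrates": int(mdr1_sub.sum()),
        "n_bcrp_substrates": int(bcrp_sub.sum()),
        "uptake_mimics": [compounds[i] for i in uptake_idx],
        "low_permeability": [compounds[i] for i in lowperm_idx],
    }
    return df, truth


def generate_invivo_kpuu(
    panel: pd.DataFrame,
    config: GeneratorConfig,
    alpha: float | None = None,
    beta: float | None = None,
    sigma: float | None = None,
) -> pd.DataFrame:
    """In vivo K_p,uu observations from the scaled-efflux generative model.

    K_p,uu = [1 / (alpha*NET_MDR1 + beta*NET_BCRP + 1)] * exp(eps) with
    eps ~ N(0, sigma^2); uptake mimics are overridden with values above the
    model's attainable range and low-permeability mimics with restricted
    values at near-zero efflux.
    """
    rng = _stage_rng(config.seed, 1)
    alpha = config.alpha_true if alpha is None else alpha
    beta = config.beta_true if beta is None else beta
    sigma = config.kpuu_noise_sigma if sigma is None else sigma

    sub = panel.iloc[: config.n_kpuu_compounds].copy()
    m = sub["net_er_hMDR1"].to_numpy()
    b = sub["net_er_hBCRP"].to_numpy()
    base = predict_kpuu_scaled(m, b, alpha, beta)
    eps = rng.normal(0.0, sigma, len(sub)) if sigma > 0 else np.zeros(len(sub))
    kpuu = base * np.exp(eps)

    uptake = (sub["archetype"] == "uptake_mimic").to_numpy()
    lowperm = (sub["archetype"] == "low_permeability").to_numpy()
    kpuu[uptake] = rng.uniform(1.4, 2.6, uptake.sum())
    kpuu[lowperm] = rng.uniform(0.05, 0.25, lowperm.sum())

    return pd.DataFrame(
        {
            "compound_id": sub["compound_id"].to_numpy(),
            "net_er_mdr1": m,
            "net_er_bcrp": b,
            "kpuu_invivo": kpuu,
            "low_permeability_flag": lowperm,
            "archetype": sub["archetype"].to_numpy(),
        }
    )


def generate_wells(
    panel: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw replicate wells plus Lucifer Yellow QC wells for the panel.

    Receiver amounts are consistent with a latent passive permeability per
    compound and the panel's ER in each line (vehicle arm) or an ER of 1
    (inhibited arm); multiplicative lognormal noise with the configured CV
    is applied per well, and per-compound recovery losses are drawn from the
    configured range (with ``n_low_recovery`` compounds forced below the 60%
    limit to exercise QC).
    """
    rng = _stage_rng(config.seed, 2)
    n = len(panel)
    lines = list(MDR1_LINES) + ["mock", "hBCRP"]

    papp_base = config.papp_passive_median * np.exp(
        rng.normal(0.0, config.papp_passive_log_sigma, n)
    )
    papp_base[(panel["archetype"] == "low_permeability").to_numpy()] = config.papp_low_perm

    loss = rng.uniform(*config.recovery_loss_range, n)
    # force a few compounds (outside the in vivo subset when possible) to
    # fail the recovery rule
    if config.n_low_recovery > 0:
        candidates = [i for i in range(n - 1, -1, -1) if i >= config.n_kpuu_compounds]
        forced = (candidates or list(range(n - 1, -1, -1)))[: config.n_low_recovery]
        loss[forced] = rng.uniform(0.45, 0.55, len(forced))

    dose = config.c0_donor_uM * config.donor_volume_mL * 1000.0  # pmol
    scale = config.t_end_min * 60.0 * config.filter_area_cm2 * config.c0_donor_uM * 1000.0

    er_cols = {line: panel[f"er_{line}"].to_numpy() for line in MDR1_LINES}
    er_cols["hBCRP"] = panel["er_hBCRP"].to_numpy()
    er_cols["mock"] = panel["er_mock"].to_numpy()

    rows = []
    ly_rows = []
    reps = config.replicates
    for i in range(n):
        cid = panel["compound_id"].iat[i]
        for line in lines:
            er_v = er_cols[line][i]
            # keep the B->A receiver below half the dose: strong substrates
            # deplete the donor, which the linear single-timepoint model
            # ignores; lowering the passive component preserves the ER
            papp_eff = min(papp_base[i], 0.5 * dose / (scale * max(er_v, 1.0)))
            for arm, er in (("vehicle", er_v), ("inhibited", 1.0)):
                papp_ab = papp_eff
                papp_ba = er * papp_ab
                for direction, papp in (("A2B", papp_ab), ("B2A", papp_ba)):
                    q_true = papp * scale
                    noise = (
                        np.exp(rng.normal(0.0, config.cv_well, reps))
                        if config.cv_well > 0
                        else np.ones(reps)
                    )
                    q = q_true * noise
                    donor = np.maximum(dose * (1.0 - loss[i]) - q, 0.0)
                    for rep in range(reps):
                        rows.append(
                            (
                                cid, line, direction, arm,
                                config.c0_donor_uM, config.t_end_min,
                                q[rep], donor[rep],
                                config.receiver_volume_mL, config.donor_volume_mL,
                                config.filter_area_cm2, rep,
                            )
                        )
            ly_fail = rng.random() < config.ly_fail_rate
            ly = rng.uniform(2.5e-6, 5e-6) if ly_fail else rng.uniform(3e-7, 1.5e-6)
            ly_rows.append((cid, line, ly))

    wells = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "cell_line", "direction", "inhibitor_arm",
            "c0_donor_uM", "t_end_min", "amount_receiver_pmol", "amount_donor_pmol",
            "receiver_volume_mL", "donor_volume_mL", "filter_area_cm2", "replicate_id",
        ],
    )
    ly = pd.DataFrame(ly_rows, columns=["compound_id", "cell_line", "ly_papp_cm_per_s"])
    return wells, ly


def generate_abundance(config: GeneratorConfig) -> pd.DataFrame:
    """Transporter abundance table (pmol/mg) for cells and brain microvessels."""
    rows = [
        {"transporter": name, "cell_abundance": cell, "brain_abundance": brain}
        for name, (cell, brain) in DEFAULT_ABUNDANCE.items()
    ]
    return pd.DataFrame(rows)


def generate_dose_response(
    config: GeneratorConfig,
) -> tuple[list[DoseResponseSeries], dict]:
    """Seven-point inhibitor titrations per ortholog and probe substrate.

    Responses follow the decreasing 4PL with the configured truths plus
    Gaussian noise; censored-truth inhibitors are generated flat (inhibition
    never reaching 50%).  Returns the series and the truth record.
    """
    rng = _stage_rng(config.seed, 3)
    if not config.ic50_truths:
        raise InvalidInputError("ic50_truths must be non-empty")
    vehicle_er = {"hMDR1": 17.7, "rMDR1": 17.2, "mMDR1": 13.9, "cyMDR1": 13.3}
    series: list[DoseResponseSeries] = []
    truth: dict = {}
    nc = config.dr_n_concentrations
    for t in config.ic50_truths:
        for substrate, shift in (("digoxin", 1.0), ("quinidine", t.quinidine_shift)):
            for line in MDR1_LINES:
                if t.censored:
                    conc = np.geomspace(0.01, 100.0, nc)
                    resp = 92.0 + (
                        rng.normal(0.0, config.dr_noise_sd_pct, nc)
                        if config.dr_noise_sd_pct > 0
                        else np.zeros(nc)
                    )
                    true_ic50 = float("nan")
                else:
                    true_ic50 = t.ic50_by_line[line] * shift
                    center = stats.gmean(
                        [v * shift for v in t.ic50_by_line.values()]
                    )
                    conc = np.geomspace(center / 100.0, center * 100.0, nc)
                    resp = four_param_logistic(conc, 100.0, 0.0, np.log10(true_ic50), t.hill)
                    if config.dr_noise_sd_pct > 0:
                        resp = resp + rng.normal(0.0, config.dr_noise_sd_pct, nc)
                er = np.maximum(resp, 1e-6) / 100.0 * vehicle_er[line]
                series.append(
                    DoseResponseSeries(
                        inhibitor_id=t.inhibitor_id,
                        substrate=substrate,
                        cell_line=line,
                        concentrations=tuple(conc),
                        er_values=tuple(er),
                        vehicle_er=vehicle_er[line],
                    )
                )
                truth[(t.inhibitor_id, substrate, line)] = {
                    "ic50": true_ic50,
                    "hill": t.hill,
                    "censored": t.censored,
                }
    return series, truth


@dataclass
class SimulatedStudy:
    """Bundle of all generated inputs plus their ground truth."""

    config: GeneratorConfig
    panel: pd.DataFrame
    panel_truth: dict
    kpuu_obs: pd.DataFrame
    wells: pd.DataFrame
    ly: pd.DataFrame
    abundance: pd.DataFrame
    dose_response: list
    dose_response_truth: dict


def simulate_study(config: GeneratorConfig) -> SimulatedStudy:
    """Generate every pipeline input for one seed."""
    panel, panel_truth = generate_efflux_panel(config)
    kpuu_obs = generate_invivo_kpuu(panel, config)
    wells, ly = generate_wells(panel, config)
    abundance = generate_abundance(config)
    dr, dr_truth = generate_dose_response(config)
    return SimulatedStudy(
        config=config,
        panel=panel,
        panel_truth=panel_truth,
        kpuu_obs=kpuu_obs,
        wells=wells,
        ly=ly,
        abundance=abundance,
        dose_response=dr,
        dose_response_truth=dr_truth,
    )
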