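"""Reduction of bidirectional transwell measurements to efflux ratios.

A bidirectional assay doses a compound on one side (apical or basolateral) of
a transporter-overexpressing MDCKII monolayer grown on a filter insert and
samples both compartments at a fixed endpoint.  The apparent permeability in
each direction yields the efflux ratio

    ER = P_app(B->A) / P_app(A->B),

and running the assay with and without a selective inhibitor (zosuquidar for
MDR1, Ko143 for BCRP) isolates the transporter-attributable component

    NET ER = ER(-inh) - ER(+inh).

NET ERs from the MDR1 and BCRP cell lines combine into a total efflux burden

    Total ER = NET ER_MDR1 + NET ER_BCRP + 1,

optionally weighted by relative expression factors (REF), the ratio of
transporter abundance in brain microvessels to abundance in the assay cell
line:

    Total ER_REF = REF_MDR1 * NET ER_MDR1 + REF_BCRP * NET ER_BCRP + 1.

Quality control follows two rules: experiments whose Lucifer Yellow marker
permeability exceeds 2e-6 cm/s are rejected (leaky monolayer), and compounds
recovering less than 60% of the dose are excluded (mass-balance failure).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedEffluxError

__all__ = [
    "CellLine",
    "Direction",
    "InhibitorArm",
    "TransportWell",
    "QCSettings",
    "EffluxRecord",
    "AbundanceEntry",
    "TotalEffluxRecord",
    "LY_PAPP_LIMIT",
    "RECOVERY_LIMIT_PCT",
    "DEFAULT_FILTER_AREA_CM2",
    "compute_papp",
    "compute_recovery",
    "compute_er",
    "net_er",
    "total_er",
    "compute_ref",
    "total_er_ref",
    "apply_qc",
    "build_efflux_table",
    "build_total_efflux_table",
]

#: Monolayer-integrity limit on Lucifer Yellow permeability (cm/s); strictly
#: greater values reject the experiment, the boundary itself is retained.
LY_PAPP_LIMIT = 2e-6

#: Mass-balance limit (%); strictly lower values exclude the compound, the
#: boundary itself is retained.
RECOVERY_LIMIT_PCT = 60.0

#: Growth area of a 96-well filter insert (cm^2); configurable per well.
DEFAULT_FILTER_AREA_CM2 = 0.11

_SECONDS_PER_MINUTE = 60.0
#: 1 uM == 1 nmol/mL == 1000 pmol/cm^3.
_PMOL_PER_CM3_PER_UM = 1000.0

#: Slack allowed on the mass-balance invariant (receiver + donor <= dose),
#: absorbing analytical noise in synthetic and real tables alike.
MASS_BALANCE_TOL = 0.10


class CellLine(str, enum.Enum):
    hMDR1 = "hMDR1"
    rMDR1 = "rMDR1"
    mMDR1 = "mMDR1"
    cyMDR1 = "cyMDR1"
    mock = "mock"
    hBCRP = "hBCRP"


class Direction(str, enum.Enum):
    A2B = "A2B"
    B2A = "B2A"


class InhibitorArm(str, enum.Enum):
    vehicle = "vehicle"
    inhibited = "inhibited"


@dataclass(frozen=True)
class TransportWell:
    """One donor/receiver measurement arm of a bidirectional assay.

    Amounts are endpoint quantities in pmol; ``c0_donor`` is the dosing
    concentration in uM; ``t_end`` in minutes; volumes in mL; area in cm^2.
    """

    compound_id: str
    cell_line: str
    direction: str
    inhibitor_arm: str
    c0_donor: float
    t_end: float
    amount_receiver_end: float
    amount_donor_end: float
    receiver_volume: float = 0.25
    donor_volume: float = 0.25
    filter_area: float = DEFAULT_FILTER_AREA_CM2
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.c0_donor <= 0:
            raise InvalidInputError("c0_donor must be > 0")
        if self.t_end <= 0:
            raise InvalidInputError("t_end must be > 0")
        if self.filter_area <= 0:
            raise InvalidInputError("filter_area must be > 0")
        if self.amount_receiver_end < 0 or self.amount_donor_end < 0:
            raise InvalidInputError("endpoint amounts must be >= 0")
        # dose in pmol: uM * mL * 1000 pmol/(mL*uM)
        dose = self.c0_donor * self.donor_volume * 1000.0
        if self.amount_receiver_end + self.amount_donor_end > dose * (1.0 + MASS_BALANCE_TOL):
            raise InvalidInputError(
                "mass balance violated: receiver + donor amounts exceed the dose"
            )

    @property
    def dose_pmol(self) -> float:
        """Dosed amount in pmol (c0 [uM] x donor volume [mL] x 1000)."""
        return self.c0_donor * self.donor_volume * 1000.0


@dataclass(frozen=True)
class QCSettings:
    """Thresholds for the two QC rules; defaults are the assay's."""

    ly_papp_limit: float = LY_PAPP_LIMIT
    recovery_limit_pct: float = RECOVERY_LIMIT_PCT


@dataclass(frozen=True)
class EffluxRecord:
    """Per compound x cell line efflux summary (means of >= 6 wells)."""

    compound_id: str
    cell_line: str
    papp_ab: float
    papp_ba: float
    er_vehicle: float
    er_inhibited: float
    net_er: float
    n_replicates: int


@dataclass(frozen=True)
class AbundanceEntry:
    """Transporter abundance (pmol/mg membrane protein) and its REF."""

    transporter: str
    cell_abundance: float
    brain_abundance: float
    ref: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cell_abundance <= 0:
            raise InvalidInputError("cell_abundance must be > 0")
        object.__setattr__(self, "ref", self.brain_abundance / self.cell_abundance)


@dataclass(frozen=True)
class TotalEffluxRecord:
    compound_id: str
    net_er_mdr1: float
    net_er_bcrp: float
    total_er: float
    total_er_ref: float


def compute_papp(
    amount_receiver_pmol: float,
    c0_donor_um: float,
    t_end_min: float,
    filter_area_cm2: float = DEFAULT_FILTER_AREA_CM2,
) -> float:
    """Single-timepoint apparent permeability in cm/s.

    P_app = Q_receiver(t) / (t * A * C0) with t in seconds, A in cm^2 and C0
    converted from uM to pmol/cm^3.  Linear in the receiver amount and
    inverse-linear in each of t, A and C0.
    """
    if t_end_min <= 0 or filter_area_cm2 <= 0 or c0_donor_um <= 0:
        raise InvalidInputError("time, area and donor concentration must be > 0")
    if amount_receiver_pmol < 0:
        raise InvalidInputError("receiver amount must be >= 0")
    t_s = t_end_min * _SECONDS_PER_MINUTE
    c0 = c0_donor_um * _PMOL_PER_CM3_PER_UM
    return amount_receiver_pmol / (t_s * filter_area_cm2 * c0)


def papp_from_well(well: TransportWell) -> float:
    """`compute_papp` applied to a :class:`TransportWell`."""
    return compute_papp(well.amount_receiver_end, well.c0_donor, well.t_end, well.filter_area)


def compute_recovery(
    amount_receiver_pmol: float, amount_donor_pmol: float, dose_pmol: float
) -> float:
    """Mass balance: percentage of the dose found in either compartment."""
    if dose_pmol <= 0:
        raise InvalidInputError("dose must be > 0")
    return 100.0 * (amount_receiver_pmol + amount_donor_pmol) / dose_pmol


def compute_er(papp_ab: float, papp_ba: float) -> float:
    """Efflux ratio P_app(B->A) / P_app(A->B); undefined when P_app(A->B) = 0."""
    if papp_ab < 0 or papp_ba < 0:
        raise InvalidInputError("permeabilities must be >= 0")
    if papp_ab == 0:
        raise UndefinedEffluxError("efflux ratio undefined for P_app(A->B) = 0")
    return papp_ba / papp_ab


def net_er(er_vehicle: float, er_inhibited: float) -> float:
    """Transporter-attributable efflux: ER(-inh) - ER(+inh), floored at 0.

    Replicate noise can push the difference slightly negative; a negative net
    efflux is non-physical and would break the downstream K_p,uu models, so
    the value is clipped to zero.
    """
    if er_vehicle <= 0 or er_inhibited <= 0:
        raise InvalidInputError("efflux ratios must be > 0")
    return max(er_vehicle - er_inhibited, 0.0)


def total_er(net_er_mdr1: float, net_er_bcrp: float) -> float:
    """Combined efflux burden of MDR1 and BCRP: NET_MDR1 + NET_BCRP + 1."""
    if net_er_mdr1 < 0 or net_er_bcrp < 0:
        raise InvalidInputError("NET ERs must be >= 0")
    return net_er_mdr1 + net_er_bcrp + 1.0


def compute_ref(brain_abundance: float, cell_abundance: float) -> float:
    """Relative expression factor: brain microvessel / cell line abundance."""
    if cell_abundance <= 0:
        raise InvalidInputError("cell_abundance must be > 0")
    if brain_abundance <= 0:
        raise InvalidInputError("brain_abundance must be > 0")
    return brain_abundance / cell_abundance


def total_er_ref(
    net_er_mdr1: float,
    net_er_bcrp: float,
    ref_mdr1: float,
    ref_bcrp: float,
) -> float:
    """REF-weighted total efflux; reduces to :func:`total_er` at unit REFs."""
    if net_er_mdr1 < 0 or net_er_bcrp < 0:
        raise InvalidInputError("NET ERs must be >= 0")
    if ref_mdr1 <= 0 or ref_bcrp <= 0:
        raise InvalidInputError("REFs must be > 0")
    return ref_mdr1 * net_er_mdr1 + ref_bcrp * net_er_bcrp + 1.0


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

WELL_COLUMNS = [
    "compound_id",
    "cell_line",
    "direction",
    "inhibitor_arm",
    "c0_donor_uM",
    "t_end_min",
    "amount_receiver_pmol",
    "amount_donor_pmol",
    "receiver_volume_mL",
    "donor_volume_mL",
    "filter_area_cm2",
    "replicate_id",
]

LY_COLUMNS = ["compound_id", "cell_line", "ly_papp_cm_per_s"]


def apply_qc(
    wells: pd.DataFrame,
    ly_table: pd.DataFrame | None = None,
    settings: QCSettings = QCSettings(),
) -> tuple[pd.DataFrame, list[dict]]:
    """Filter a well table by the two QC rules and log every exclusion.

    Rule 1 (monolayer integrity): an experiment, keyed by
    ``(compound_id, cell_line)``, with Lucifer Yellow P_app strictly above the
    limit is rejected wholesale.

    Rule 2 (mass balance): a ``(compound_id, cell_line)`` whose mean recovery
    is strictly below the limit is excluded.

    Returns the retained wells (recovery column added) and a list of
    exclusion-log entries; the log partitions the input exactly — no well is
    both retained and logged.
    """
    wells = wells.copy()
    dose = wells["c0_donor_uM"] * wells["donor_volume_mL"] * 1000.0
    wells["recovery_pct"] = (
        100.0 * (wells["amount_receiver_pmol"] + wells["amount_donor_pmol"]) / dose
    )

    log: list[dict] = []
    rejected = pd.Series(False, index=wells.index)
    key = list(zip(wells["compound_id"], wells["cell_line"]))

    if ly_table is not None and len(ly_table):
        failed = ly_table[ly_table["ly_papp_cm_per_s"] > settings.ly_papp_limit]
        failed_keys = set(zip(failed["compound_id"], failed["cell_line"]))
        for _, row in failed.iterrows():
            log.append(
                {
                    "reason": "ly_papp_above_limit",
                    "compound_id": row["compound_id"],
                    "cell_line": row["cell_line"],
                    "value": float(row["ly_papp_cm_per_s"]),
                    "limit": settings.ly_papp_limit,
                }
            )
        rejected |= pd.Series([k in failed_keys for k in key], index=wells.index)

    mean_recovery = wells[~rejected].groupby(["compound_id", "cell_line"])[
        "recovery_pct"
    ].mean()
    low = mean_recovery[mean_recovery < settings.recovery_limit_pct]
    low_keys = set(low.index)
    for (cid, line), val in low.items():
        log.append(
            {
                "reason": "recovery_below_limit",
                "compound_id": cid,
                "cell_line": line,
                "value": float(val),
                "limit": settings.recovery_limit_pct,
            }
        )
    rejected |= pd.Series([k in low_keys for k in key], index=wells.index)

    return wells[~rejected].reset_index(drop=True), log


def build_efflux_table(
    wells: pd.DataFrame,
    ly_table: pd.DataFrame | None = None,
    settings: QCSettings = QCSettings(),
) -> tuple[pd.DataFrame, list[dict]]:
    """QC-filter wells and reduce them to per (compound, cell line) efflux.

    Well-level P_app values are averaged per (compound, cell line, direction,
    arm) and the efflux ratios are formed from the replicate-mean
    permeabilities, so each reported ER is the mean of at least six wells per
    direction.  Returns a DataFrame with columns matching
    :class:`EffluxRecord` plus the QC exclusion log.
    """
    kept, log = apply_qc(wells, ly_table, settings)
    if not len(kept):
        cols = [
            "compound_id", "cell_line", "papp_ab", "papp_ba",
            "er_vehicle", "er_inhibited", "net_er", "n_replicates",
        ]
        return pd.DataFrame(columns=cols), log

    kept = kept.copy()
    t_s = kept["t_end_min"] * _SECONDS_PER_MINUTE
    c0 = kept["c0_donor_uM"] * _PMOL_PER_CM3_PER_UM
    kept["papp"] = kept["amount_receiver_pmol"] / (t_s * kept["filter_area_cm2"] * c0)

    grouped = (
        kept.groupby(["compound_id", "cell_line", "inhibitor_arm", "direction"])["papp"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "papp", "size": "n"})
        .reset_index()
    )
    wide = grouped.pivot_table(
        index=["compound_id", "cell_line"],
        columns=["inhibitor_arm", "direction"],
        values=["papp", "n"],
        aggfunc="first",
    )

    records = []
    for (cid, line), row in wide.iterrows():
        try:
            papp_ab_v = row[("papp", "vehicle", "A2B")]
            papp_ba_v = row[("papp", "vehicle", "B2A")]
            papp_ab_i = row[("papp", "inhibited", "A2B")]
            papp_ba_i = row[("papp", "inhibited", "B2A")]
        except KeyError:
            continue
        if any(pd.isna(v) for v in (papp_ab_v, papp_ba_v, papp_ab_i, papp_ba_i)):
            continue
        er_v = compute_er(papp_ab_v, papp_ba_v)
        er_i = compute_er(papp_ab_i, papp_ba_i)
        n_min = int(
            min(
                row[("n", "vehicle", "A2B")],
                row[("n", "vehicle", "B2A")],
                row[("n", "inhibited", "A2B")],
                row[("n", "inhibited", "B2A")],
            )
        )
        records.append(
            {
                "compound_id": cid,
                "cell_line": line,
                "papp_ab": papp_ab_v,
                "papp_ba": papp_ba_v,
                "er_vehicle": er_v,
                "er_inhibited": er_i,
                "net_er": net_er(er_v, er_i),
                "n_replicates": n_min,
            }
        )
    return pd.DataFrame(records), log


def build_total_efflux_table(
    efflux: pd.DataFrame,
    ref_mdr1: float,
    ref_bcrp: float,
    mdr1_line: str = "hMDR1",
    bcrp_line: str = "hBCRP",
) -> pd.DataFrame:
    """Combine MDR1 and BCRP NET ERs into total and REF-corrected total ERs.

    Compounds missing either cell line contribute a NET ER of 0 for the
    missing transporter (non-substrate by absence of evidence is not assumed;
    compounds absent from both lines are dropped).
    """
    mdr1 = efflux[efflux["cell_line"] == mdr1_line].set_index("compound_id")["net_er"]
    bcrp = efflux[efflux["cell_line"] == bcrp_line].set_index("compound_id")["net_er"]
    compounds = sorted(set(mdr1.index) | set(bcrp.index))
    rows = []
    for cid in compounds:
        m = float(mdr1.get(cid, 0.0))
        b = float(bcrp.get(cid, 0.0))
        rows.append(
            {
                "compound_id": cid,
                "net_er_mdr1": m,
                "net_er_bcrp": b,
                "total_er": total_er(m, b),
                "total_er_ref": total_er_ref(m, b, ref_mdr1, ref_bcrp),
            }
        )
    return pd.DataFrame(rows)
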