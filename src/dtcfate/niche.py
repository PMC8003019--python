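"""Descriptive statistics of DTC niche association in bone.

Each disseminated tumour cell (DTC) carries three distances measured on
tissue sections - to the growth plate, to the nearest blood vessel and to
the nearest bone surface (all in micrometres) - plus the subtype of the
nearest vessel (type-H, CD31-high / type-L, CD31-low; ``none`` when the
cell is not vessel-associated).  A cell is "associated" with a compartment
when its distance to it is at or below a contact radius (default 10 um; the
association criterion is an operational choice, exposed as a parameter
everywhere).  The four association categories

    perivascular (vessel only), endosteal (bone only), overlapping, neither

partition every valid observation.

The animal, not the cell, is the unit of replication: proportions are
computed per animal and then averaged across animals, SEMs and two-sample
Student's t-tests are taken over animals.  Cell-level pooling is available
via ``per_animal=False`` where noted but is not the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NicheObservation",
    "NicheSummary",
    "TTestResult",
    "NICHE_CATEGORIES",
    "VESSEL_TYPES",
    "DEFAULT_CONTACT_RADIUS",
    "GROWTH_PLATE_MAX",
    "classify_niche",
    "per_animal_table",
    "summarize",
    "compare_groups",
    "compare_all_categories",
    "distance_profile",
]

logger = logging.getLogger(__name__)

NICHE_CATEGORIES = ("perivascular", "endosteal", "overlapping", "neither")
VESSEL_TYPES = ("H", "L", "none")
DEFAULT_CONTACT_RADIUS = 10.0  # um
GROWTH_PLATE_MAX = 200.0  # um; DTCs home within this band below the growth plate


@dataclass(frozen=True)
class NicheObservation:
    """Spatial measurements for a single DTC."""

    dtc_id: str
    subject_id: str
    group: str
    distance_to_growth_plate: float  # um
    distance_to_vessel: float  # um
    distance_to_bone: float  # um
    vessel_type: str  # 'H', 'L' or 'none'


@dataclass
class NicheSummary:
    """Per-group niche association summary, animal as replication unit."""

    group: str
    n_animals: int
    #: category -> (mean proportion across animals, SEM)
    proportions: dict
    #: (mean, SEM) of the type-H fraction among vessel-associated DTCs
    vessel_h_fraction: tuple
    distance_mean: float
    distance_median: float
    distance_sem: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def _valid(obs: NicheObservation) -> bool:
    for v in (obs.distance_to_growth_plate, obs.distance_to_vessel, obs.distance_to_bone):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v < 0:
            return False
    return True


def classify_niche(
    obs: NicheObservation, contact_radius: float = DEFAULT_CONTACT_RADIUS
) -> str:
    """Assign one of the four association categories to a DTC.

    Raises ``ValueError`` on missing or negative distances; callers that
    process tables exclude such records with a logged count instead.
    """
    if not _valid(obs):
        raise ValueError(f"observation {obs.dtc_id!r} has missing or invalid distances")
    near_vessel = obs.distance_to_vessel <= contact_radius
    near_bone = obs.distance_to_bone <= contact_radius
    if near_vessel and near_bone:
        return "overlapping"
    if near_vessel:
        return "perivascular"
    if near_bone:
        return "endosteal"
    return "neither"


def observations_to_frame(observations: Sequence[NicheObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dtc_id": [o.dtc_id for o in observations],
            "subject_id": [o.subject_id for o in observations],
            "group": [o.group for o in observations],
            "distance_to_growth_plate": [o.distance_to_growth_plate for o in observations],
            "distance_to_vessel": [o.distance_to_vessel for o in observations],
            "distance_to_bone": [o.distance_to_bone for o in observations],
            "vessel_type": [o.vessel_type for o in observations],
        }
    )


def observations_from_frame(df: pd.DataFrame) -> list[NicheObservation]:
    return [
        NicheObservation(
            dtc_id=str(r.dtc_id),
            subject_id=str(r.subject_id),
            group=str(r.group),
            distance_to_growth_plate=float(r.distance_to_growth_plate),
            distance_to_vessel=float(r.distance_to_vessel),
            distance_to_bone=float(r.distance_to_bone),
            vessel_type=str(r.vessel_type),
        )
        for r in df.itertuples(index=False)
    ]


def per_animal_table(
    observations: Sequence[NicheObservation],
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
) -> pd.DataFrame:
    """One row per animal: category proportions, type-H fraction, distances.

    Records with missing distances are excluded with a logged count.
    """
    valid = [o for o in observations if _valid(o)]
    dropped = len(observations) - len(valid)
    if dropped:
        logger.warning("per_animal_table: excluded %d records with invalid distances", dropped)
    if not valid:
        raise ValueError("no valid observations")
    df = observations_to_frame(valid)
    near_v = df["distance_to_vessel"] <= contact_radius
    near_b = df["distance_to_bone"] <= contact_radius
    df["category"] = np.select(
        [near_v & near_b, near_v, near_b],
        ["overlapping", "perivascular", "endosteal"],
        default="neither",
    )
    rows = []
    for (group, subject), g in df.groupby(["group", "subject_id"], sort=True):
        n = len(g)
        counts = g["category"].value_counts()
        row = {"group": group, "subject_id": subject, "n_dtcs": n}
        for cat in NICHE_CATEGORIES:
            row[cat] = counts.get(cat, 0) / n
        vessel_assoc = g[g["category"].isin(["perivascular", "overlapping"])]
        row["vessel_h_fraction"] = (
            float((vessel_assoc["vessel_type"] == "H").mean())
            if len(vessel_assoc)
            else np.nan
        )
        row["gp_distance_mean"] = float(g["distance_to_growth_plate"].mean())
        row["gp_distance_median"] = float(g["distance_to_growth_plate"].median())
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_sem(values: np.ndarray, what: str) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan, math.nan
    if values.size == 1:
        logger.warning("summarize: single animal for %s, SEM reported as 0", what)
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


def summarize(
    observations: Sequence[NicheObservation],
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
) -> dict[str, NicheSummary]:
    """Per-group niche summaries; proportions averaged across animals."""
    table = per_animal_table(observations, contact_radius)
    out: dict[str, NicheSummary] = {}
    for group, g in table.groupby("group", sort=True):
        props = {
            cat: _mean_sem(g[cat].to_numpy(float), f"{group}/{cat}")
            for cat in NICHE_CATEGORIES
        }
        vh = _mean_sem(g["vessel_h_fraction"].to_numpy(float), f"{group}/vessel_h")
        d_mean, d_sem = _mean_sem(g["gp_distance_mean"].to_numpy(float), f"{group}/distance")
        d_median = float(np.median(g["gp_distance_median"]))
        out[str(group)] = NicheSummary(
            group=str(group),
            n_animals=len(g),
            proportions=props,
            vessel_h_fraction=vh,
            distance_mean=d_mean,
            distance_median=d_median,
            distance_sem=d_sem,
        )
    return out


def _two_groups(table: pd.DataFrame, group_a: Optional[str], group_b: Optional[str]):
    groups = sorted(table["group"].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, found {groups}; pass group_a/group_b")
        group_a, group_b = groups
    return group_a, group_b


def compare_groups(
    observations: Sequence[NicheObservation],
    category: str,
    *,
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    alternative: str = "two-sided",
) -> TTestResult:
    """Two-sample Student's t-test on per-animal proportions of a category.

    Requires at least two animals per group.  Two-tailed by default; the
    two-tailed p-value is symmetric under swapping the groups.
    """
    if category not in NICHE_CATEGORIES and category != "vessel_h_fraction":
        raise ValueError(f"unknown category {category!r}")
    table = per_animal_table(observations, contact_radius)
    group_a, group_b = _two_groups(table, group_a, group_b)
    a = table.loc[table["group"] == group_a, category].dropna().to_numpy(float)
    b = table.loc[table["group"] == group_b, category].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two animals per group for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    df = len(a) + len(b) - 2
    if math.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    return TTestResult(statistic=float(t), df=float(df), pvalue=float(p))


def compare_all_categories(
    observations: Sequence[NicheObservation],
    *,
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
) -> pd.DataFrame:
    """t-tests for every category; raw p-values plus a Holm-adjusted column."""
    rows = []
    for cat in NICHE_CATEGORIES:
        r = compare_groups(
            observations, cat, group_a=group_a, group_b=group_b,
            contact_radius=contact_radius,
        )
        rows.append({"category": cat, "t": r.statistic, "df": r.df, "pvalue": r.pvalue})
    df = pd.DataFrame(rows)
    df["pvalue_holm"] = multipletests(df["pvalue"], method="holm")[1]
    return df


def distance_profile(
    observations: Sequence[NicheObservation],
    bin_width: float,
    max_distance: float = GROWTH_PLATE_MAX,
) -> pd.DataFrame:
    """Histogram of DTC distance to the growth plate per group.

    Bins cover [0, max_distance]; the last bin is closed on the right so
    counts sum to the number of observations with a valid distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, max_distance, bin_width)
    edges = np.append(edges, max_distance)
    rows = []
    valid = [o for o in observations if _valid(o)]
    dropped = len(observations) - len(valid)
    if dropped:
        logger.warning("distance_profile: excluded %d records with invalid distances", dropped)
    groups = sorted({o.group for o in valid})
    for group in groups:
        d = np.array([o.distance_to_growth_plate for o in valid if o.group == group])
        counts, _ = np.histogram(d, bins=edges)
        for i, c in enumerate(counts):
            rows.append(
                {"group": group, "bin_left": edges[i], "bin_right": edges[i + 1],
                 "count": int(c)}
            )
    if not rows:  # empty input: emit an all-zero profile with no group label
        counts = np.zeros(len(edges) - 1, dtype=int)
        rows = [
            {"group": "", "bin_left": edges[i], "bin_right": edges[i + 1], "count": 0}
            for i in range(len(counts))
        ]
    return pd.DataFrame(rows)
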