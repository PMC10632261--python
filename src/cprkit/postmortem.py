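"""Post-mortem lung analyses: wet-dry edema ratio, per-region group
comparisons with Bonferroni correction, and visual-grading summaries.

Histopathology samples come from ten standard locations (paracardiac,
upper/lower x ventral/dorsal, left and right); continuous measures
(atelectasis %, hyperinflation %, edema grade, wet-dry ratio) are compared
per location with the exact Mann-Whitney test and binary measures
(microscopic hemorrhage) with Fisher's exact test, adjusting across the
locations actually tested.  A synthetic table generator (beta-distributed
percentages, ordinal grades with an optional group shift) stands in for
real gradings so the pipeline is testable without animal data; it is
synthetic by construction and labelled as such.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bonferroni_adjust, fisher_exact_2x2, mann_whitney_exact

log = logging.getLogger(__name__)

LUNG_REGIONS = ("paracardiac", "upper_ventral", "upper_dorsal",
                "lower_ventral", "lower_dorsal")
LUNG_SIDES = ("left", "right")
LUNG_LOCATIONS = tuple(f"{r}_{s}" for r in LUNG_REGIONS for s in LUNG_SIDES)
INJURY_TYPES = ("atelectasis", "hyperinflation", "hemorrhage")


def wet_dry_ratio(wet: float, dry: float) -> float:
    """Lung-water index wet mass / dry mass; requires 0 < dry <= wet."""
    if not dry > 0:
        raise ValueError("dry mass must be positive")
    if wet < dry:
        raise ValueError("wet mass must be >= dry mass")
    return wet / dry


def water_fraction(wet: float, dry: float) -> float:
    """Secondary edema index (wet - dry) / wet."""
    wet_dry_ratio(wet, dry)
    return (wet - dry) / wet


def compare_regions(
    samples: pd.DataFrame, measure: str, binary: bool | None = None
) -> pd.DataFrame:
    """Per-location group comparison of ``measure`` with Bonferroni
    adjustment across the locations tested.

    ``samples`` needs columns subject, group, location and the measure.
    Locations missing a group are skipped with a log message.  Binary
    measures (auto-detected as {0,1}-valued unless ``binary`` is given) use
    Fisher's exact test on incidence; continuous ones the exact
    Mann-Whitney test.
    """
    groups = sorted(samples["group"].unique(), key=str)
    if len(groups) != 2:
        raise ValueError("expected exactly 2 groups")
    if binary is None:
        vals = samples[measure].dropna().unique()
        binary = set(np.unique(vals)).issubset({0, 1, 0.0, 1.0})
    rows = []
    for loc, sub in samples.groupby("location", sort=True):
        by_group = {g: sub.loc[sub["group"] == g, measure].dropna() for g in groups}
        if any(len(v) == 0 for v in by_group.values()):
            log.info("skipping location %s: group missing", loc)
            continue
        a, b = by_group[groups[0]], by_group[groups[1]]
        if binary:
            tab = [[int((a == 1).sum()), int((a != 1).sum())],
                   [int((b == 1).sum()), int((b != 1).sum())]]
            res = fisher_exact_2x2(tab)
        else:
            res = mann_whitney_exact(a.to_numpy(), b.to_numpy())
        rows.append({
            "location": loc, "measure": measure, "test": res.method,
            "statistic": res.statistic, "p_raw": res.p_value,
            f"median_{groups[0]}": float(np.median(a)),
            f"median_{groups[1]}": float(np.median(b)),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bonferroni_adjust(out["p_raw"].to_numpy(), m=len(out))
    return out


def incidence_summary(gradings: pd.DataFrame) -> pd.DataFrame:
    """Per-group incidence (grade > 0) and median grade per injury type.

    ``gradings`` has one row per subject with columns subject, group and the
    injury-type grades (0-3); duplicated subjects raise."""
    if gradings["subject"].duplicated().any():
        raise ValueError("duplicate subject in grading table")
    rows = []
    for grp, sub in gradings.groupby("group", sort=True):
        n = len(sub)
        for injury in INJURY_TYPES:
            if injury not in sub.columns:
                continue
            g = sub[injury].astype(float)
            rows.append({
                "group": grp, "injury": injury, "n": n,
                "incidence": int((g > 0).sum()),
                "median_grade": float(g.median()),
            })
    return pd.DataFrame(rows)


def simulate_postmortem_tables(
    n_per_group: int = 8,
    seed: int = 0,
    group_shift: float = 0.0,
    group_labels: tuple[str, str] = ("CCC", "30:2"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic post-mortem tables (histopathology, visual gradings,
    wet-dry samples) for pipeline tests; no real data behind them.

    ``group_shift`` adds a location-independent mean shift (in latent units)
    to the first group's continuous measures, zero giving a true null.
    """
    rng = np.random.default_rng(seed)
    hist_rows, grad_rows, wd_rows = [], [], []
    for g, lab in enumerate(group_labels):
        shift = group_shift if g == 0 else 0.0
        for i in range(n_per_group):
            sid = f"{lab}_{i + 1:02d}"
            for loc in LUNG_LOCATIONS:
                atel = 100 * np.clip(rng.beta(2.0, 3.0) + shift, 0.0, 1.0)
                hyper = 100 * np.clip(rng.beta(1.5, 6.0) + shift, 0.0, 1.0)
                edema = int(np.clip(round(rng.normal(2.0 + 3 * shift, 1.0)), 0, 5))
                hem = int(rng.random() < min(0.99, 0.3 + shift))
                wet = float(np.clip(rng.normal(2.2, 0.3), 1.2, 3.5))
                ratio = float(np.clip(rng.normal(5.5 + 4 * shift, 0.6), 3.0, 9.0))
                dry = wet / ratio
                hist_rows.append({
                    "subject": sid, "group": lab, "location": loc,
                    "atelectasis_pct": atel,
                    "atelectasis_pattern": rng.choice(["patchy", "homogeneous"]),
                    "hyperinflation_pct": hyper,
                    "edema_grade": edema, "micro_hemorrhage": hem,
                })
                wd_rows.append({
                    "subject": sid, "group": lab, "location": loc,
                    "wet_mass_g": wet, "dry_mass_g": dry,
                    "ratio": wet / dry,
                })
            grad_rows.append({
                "subject": sid, "group": lab,
                "atelectasis": int(np.clip(round(rng.normal(1.5 + 2 * shift, 0.8)), 0, 3)),
                "hyperinflation": int(np.clip(round(rng.normal(1.5 + 2 * shift, 0.8)), 0, 3)),
                "hemorrhage": int(np.clip(round(rng.normal(1.0 + 2 * shift, 0.8)), 0, 3)),
            })
    return (pd.DataFrame(hist_rows), pd.DataFrame(grad_rows), pd.DataFrame(wd_rows))
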