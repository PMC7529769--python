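"""Synthetic longitudinal cohort generator.

Emulates the design of a multi-year multiomics cohort: subjects visit
roughly quarterly, visit days spread uniformly over the calendar year,
each subject carries a fixed insulin-resistance status (IR/IS), BMI and
age. Analyte values are built from two seasonal archetypes — a
late-April peak and a December peak with a spring/early-summer trough —
plus subject-level random baselines, optional group effects confined to
a window of the year, and Gaussian noise. A companion generator emits
per-visit taxon count tables whose expected richness is higher in
winter than in summer.

Every generator is deterministic given the design seed, and every
generated feature is described by one row of ground truth so that
downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PERIOD = 365
#: days counted as "winter" / "summer" for richness contrasts
WINTER_DAYS = np.r_[np.arange(1, 61), np.arange(335, 366)]
SUMMER_DAYS = np.arange(152, 245)

#: archetype bump centers (day of year): late April and mid December
ARCHETYPE_CENTERS = {1: 115.0, 2: 350.0}
#: von Mises concentration giving a full width at half maximum of ~120 days
_FWHM_DAYS = 120.0
_KAPPA = np.log(2.0) / (1.0 - np.cos(2.0 * np.pi * (_FWHM_DAYS / 2.0) / PERIOD))
#: secondary bump center for the twice-a-year ("bimodal") shape
_BIMODAL_CENTERS = (115.0, 297.0)

FEATURE_KINDS = ("seasonal_p1", "seasonal_p2", "bimodal", "null", "differential")


class DesignError(ValueError):
    """Raised when a cohort design or feature specification is invalid."""


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the synthetic cohort.

    Defaults are desk scale (40 subjects, 3 years, quarterly visits);
    :func:`full_cohort` returns a preset mirroring the 105-subject study.
    """

    n_subjects: int = 40
    n_years: int = 3
    visits_per_year: int = 4
    frac_ir: float = 0.5
    bmi_mean: float = 28.0
    bmi_sd: float = 4.0
    age_range: tuple[float, float] = (25.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DesignError("n_subjects must be >= 1")
        if self.n_years < 1 or self.visits_per_year < 1:
            raise DesignError("n_years and visits_per_year must be >= 1")
        if not 0.0 <= self.frac_ir <= 1.0:
            raise DesignError("frac_ir must lie in [0, 1]")
        if self.bmi_sd < 0:
            raise DesignError("bmi_sd must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise DesignError("age_range must be (low, high)")


def full_cohort(seed: int = 0) -> CohortDesign:
    """Preset at the scale of the profiled cohort: 105 subjects over 4 years."""
    return CohortDesign(n_subjects=105, n_years=4, visits_per_year=4,
                        frac_ir=35.0 / 66.0, seed=seed)


@dataclass(frozen=True)
class FeatureSpec:
    """Recipe for one synthetic analyte.

    ``amplitude`` is in units of the standardized archetype (mean 0, sd 1
    over the year), so amplitude / noise_sd is the per-observation SNR.
    ``diff_window`` is an inclusive day-of-year pair; ``None`` means the
    group effect (if any) is active all year.
    """

    feature_id: str
    kind: str = "null"
    pattern: int | None = None
    amplitude: float = 3.0
    phase_jitter: float = 10.0
    noise_sd: float = 1.0
    subject_sd: float = 1.0
    bmi_beta: float = 0.0
    diff_window: tuple[int, int] | None = None
    diff_effect: float = 0.0
    ome: str = "omics"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise DesignError(f"unknown feature kind {self.kind!r}")
        if self.amplitude < 0:
            raise DesignError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")
        if self.subject_sd < 0:
            raise DesignError("subject_sd must be >= 0")
        if self.diff_window is not None:
            lo, hi = self.diff_window
            if not (1 <= lo <= PERIOD and 1 <= hi <= PERIOD):
                raise DesignError("diff_window days must lie in [1, 365]")


def _vm_bump(day: np.ndarray, center: float) -> np.ndarray:
    theta = 2.0 * np.pi * (np.asarray(day, dtype=float) - center) / PERIOD
    return np.exp(_KAPPA * (np.cos(theta) - 1.0))


def _standardizer(raw: "callable") -> tuple[float, float]:
    grid = np.arange(1, PERIOD + 1, dtype=float)
    vals = raw(grid)
    return float(vals.mean()), float(vals.std())


_ARCH_NORM = {
    pid: _standardizer(lambda d, c=c: _vm_bump(d, c))
    for pid, c in ARCHETYPE_CENTERS.items()
}
_BIMODAL_NORM = _standardizer(
    lambda d: _vm_bump(d, _BIMODAL_CENTERS[0]) + 0.8 * _vm_bump(d, _BIMODAL_CENTERS[1])
)


def archetype_curve(pattern_id: int, day) -> np.ndarray | float:
    """Standardized seasonal archetype value at ``day`` (period 365).

    Pattern 1 peaks in late April (day ~115); pattern 2 peaks in
    December (day ~350) and bottoms out in the March–July stretch.
    The curve is smooth and periodic, z-scored over days 1..365, so its
    values are in SD units of the annual cycle.
    """
    if pattern_id not in ARCHETYPE_CENTERS:
        raise DesignError(f"unknown archetype pattern {pattern_id!r}")
    mu, sd = _ARCH_NORM[pattern_id]
    out = (_vm_bump(np.asarray(day, dtype=float), ARCHETYPE_CENTERS[pattern_id]) - mu) / sd
    return out if np.ndim(day) else float(out)


def _bimodal_curve(day) -> np.ndarray:
    mu, sd = _BIMODAL_NORM
    d = np.asarray(day, dtype=float)
    raw = _vm_bump(d, _BIMODAL_CENTERS[0]) + 0.8 * _vm_bump(d, _BIMODAL_CENTERS[1])
    return (raw - mu) / sd


def day_of_year(dates) -> np.ndarray:
    """Calendar day-of-year clamped to [1, 365] (leap day 366 -> 365)."""
    doy = pd.DatetimeIndex(pd.to_datetime(dates)).dayofyear.to_numpy()
    return np.minimum(doy, PERIOD)


def generate_visits(design: CohortDesign) -> pd.DataFrame:
    """Draw the visit table for a design.

    Each subject receives ``n_years * visits_per_year`` visits; visit
    days are i.i.d. uniform on {1..365} (the cohort's collections were
    spread roughly evenly over the year). Group labels are assigned so
    that round(frac_ir * n_subjects) subjects are IR.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    width = max(3, len(str(n)))
    subjects = np.array([f"S{i + 1:0{width}d}" for i in range(n)])

    n_ir = int(round(design.frac_ir * n))
    group_by_subject = np.array(["IS"] * n, dtype=object)
    ir_idx = rng.choice(n, size=n_ir, replace=False)
    group_by_subject[ir_idx] = "IR"
    bmi = rng.normal(design.bmi_mean, design.bmi_sd, size=n)
    age = rng.uniform(design.age_range[0], design.age_range[1], size=n)

    rows = []
    for i, sid in enumerate(subjects):
        for year in range(design.n_years):
            days = rng.integers(1, PERIOD + 1, size=design.visits_per_year)
            for v, d in enumerate(days):
                rows.append((f"{sid}_y{year + 1}v{v + 1}", sid, int(d), year + 1,
                             group_by_subject[i], bmi[i], age[i]))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "day_of_year", "year_index",
                       "group", "bmi", "age"])


def _window_weight(day: np.ndarray, window: tuple[int, int] | None,
                   ramp: float = 15.0) -> np.ndarray:
    """Smooth 0..1 activation of a day window, raised-cosine ramped.

    Supports wrap-around windows (start > end, e.g. (335, 60)).
    """
    d = np.asarray(day, dtype=float)
    if window is None:
        return np.ones_like(d)
    lo, hi = float(window[0]), float(window[1])
    span = (hi - lo) % PERIOD
    if span == 0:
        span = PERIOD
    # position within window measured forward from lo, on the circle
    pos = (d - lo) % PERIOD
    w = np.zeros_like(d)
    inside = pos <= span
    ramp = min(ramp, span / 2.0)
    p = pos[inside]
    up = np.clip(p / ramp, 0.0, 1.0) if ramp > 0 else np.ones_like(p)
    down = np.clip((span - p) / ramp, 0.0, 1.0) if ramp > 0 else np.ones_like(p)
    w[inside] = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
    # fully-inside plateau: weight 1
    plateau = inside.copy()
    plateau[inside] = (p >= ramp) & (p <= span - ramp)
    w[plateau] = 1.0
    return w


def _base_curve(spec: FeatureSpec, day: np.ndarray, jitter: float) -> np.ndarray:
    d = np.asarray(day, dtype=float) - jitter
    if spec.kind == "seasonal_p1" or (spec.kind == "differential" and spec.pattern == 1):
        return spec.amplitude * np.asarray(archetype_curve(1, d))
    if spec.kind == "seasonal_p2" or (spec.kind == "differential" and spec.pattern == 2):
        return spec.amplitude * np.asarray(archetype_curve(2, d))
    if spec.kind == "bimodal":
        return spec.amplitude * _bimodal_curve(d)
    return np.zeros_like(d, dtype=float)


def generate_features(
    design: CohortDesign,
    specs: Sequence[FeatureSpec],
    visits: pd.DataFrame | None = None,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format analyte table plus ground truth.

    value = subject baseline + amplitude * archetype(day - jitter)
            + bmi_beta * (BMI - design mean) + group effect (IR only,
            ramped inside diff_window) + N(0, noise_sd).

    Returns ``(long, truth)``: one row per (visit, feature), and one
    ground-truth row per feature (kind, pattern, window, effect).
    """
    if not specs:
        raise DesignError("specs must be non-empty")
    if visits is None:
        visits = generate_visits(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xFEA7]))

    day = visits["day_of_year"].to_numpy(dtype=float)
    is_ir = (visits["group"] == "IR").to_numpy()
    bmi_c = visits["bmi"].to_numpy(dtype=float) - design.bmi_mean
    subj_codes, subj_index = pd.factorize(visits["subject_id"])

    frames, truth_rows = [], []
    for spec in specs:
        jitter = rng.uniform(-spec.phase_jitter, spec.phase_jitter) if spec.phase_jitter else 0.0
        baselines = rng.normal(0.0, spec.subject_sd, size=len(subj_index))
        y = baselines[subj_codes] + _base_curve(spec, day, jitter) + spec.bmi_beta * bmi_c
        if spec.kind == "differential" and spec.diff_effect != 0.0:
            y = y + spec.diff_effect * _window_weight(day, spec.diff_window) * is_ir
        y = y + rng.normal(0.0, spec.noise_sd, size=len(day))
        if missing_rate > 0:
            y = np.where(rng.random(len(day)) < missing_rate, np.nan, y)
        frames.append(pd.DataFrame({
            "sample_id": visits["sample_id"], "subject_id": visits["subject_id"],
            "day_of_year": visits["day_of_year"], "year_index": visits["year_index"],
            "group": visits["group"], "bmi": visits["bmi"], "age": visits["age"],
            "feature_id": spec.feature_id, "ome": spec.ome, "value": y}))
        win = spec.diff_window if spec.diff_window is not None else (1, PERIOD)
        truth_rows.append((spec.feature_id, spec.kind,
                           spec.pattern if spec.pattern is not None else
                           (1 if spec.kind == "seasonal_p1" else 2 if spec.kind == "seasonal_p2" else 0),
                           win[0], win[1], spec.diff_effect, jitter))
    long = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=[
        "feature_id", "kind", "pattern", "diff_window_start", "diff_window_end",
        "diff_effect", "phase_jitter_drawn"])
    return long, truth


def default_feature_panel(
    n_features: int = 200,
    frac_p1: float = 0.25,
    frac_p2: float = 0.25,
    frac_bimodal: float = 0.05,
    frac_differential: float = 0.10,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    subject_sd: float = 1.0,
    phase_jitter: float = 10.0,
    diff_effect: float = 2.0,
    diff_window: tuple[int, int] = (120, 210),
) -> list[FeatureSpec]:
    """Mixed panel: two seasonal archetypes, a bimodal shape, IR/IS
    differential features, and non-seasonal nulls for the remainder."""
    counts = {
        "seasonal_p1": int(round(frac_p1 * n_features)),
        "seasonal_p2": int(round(frac_p2 * n_features)),
        "bimodal": int(round(frac_bimodal * n_features)),
        "differential": int(round(frac_differential * n_features)),
    }
    counts["null"] = n_features - sum(counts.values())
    if counts["null"] < 0:
        raise DesignError("fractions exceed 1")
    specs: list[FeatureSpec] = []
    i = 0
    for kind, n in counts.items():
        for _ in range(n):
            i += 1
            specs.append(FeatureSpec(
                feature_id=f"f{i:04d}", kind=kind,
                pattern=1 if kind in ("seasonal_p1", "differential") else
                        2 if kind == "seasonal_p2" else None,
                amplitude=amplitude if kind in ("seasonal_p1", "seasonal_p2", "bimodal") else 0.0,
                phase_jitter=phase_jitter, noise_sd=noise_sd, subject_sd=subject_sd,
                diff_window=diff_window if kind == "differential" else None,
                diff_effect=diff_effect if kind == "differential" else 0.0))
    return specs


# ---------------------------------------------------------------------------
# microbiome counts

def _winter_weight(day: np.ndarray) -> np.ndarray:
    """Smooth 0..1 weight peaking at the turn of the year (day 365/1)."""
    bump = _vm_bump(np.asarray(day, dtype=float), 365.0)
    return bump / _vm_bump(np.array([365.0]), 365.0)[0]


def generate_taxon_counts(
    design: CohortDesign,
    visits: pd.DataFrame | None = None,
    n_taxa: int = 120,
    winter_richness_boost: float = 1.5,
    depth: int = 8000,
    base_active_frac: float = 0.45,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-visit multinomial taxon counts with season-varying richness.

    The number of taxa present in a sample follows a smooth annual
    cycle: in deep winter it is ``winter_richness_boost`` times the
    mid-summer level (capped at the taxon pool size). Which taxa are
    present is drawn per visit by perturbed-rank sampling over a
    geometric base-abundance profile, then ``depth`` reads are drawn
    multinomially. Returns ``(counts, taxonomy)``: counts indexed by
    sample_id with one column per taxon, and a lineage table with
    genus/family/order/class/phylum for each taxon.
    """
    if n_taxa < 2:
        raise DesignError("n_taxa must be >= 2")
    if depth <= 0:
        raise DesignError("depth must be positive")
    if visits is None:
        visits = generate_visits(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x7A0A]))

    base_logit = -np.arange(n_taxa) / (n_taxa / 3.0)  # geometric abundance decay
    w = _winter_weight(visits["day_of_year"].to_numpy())
    active_frac = np.minimum(base_active_frac * (1.0 + (winter_richness_boost - 1.0) * w), 1.0)
    counts = np.zeros((len(visits), n_taxa), dtype=int)
    for i in range(len(visits)):
        m = max(2, int(round(active_frac[i] * n_taxa)))
        score = base_logit + rng.gumbel(0.0, 0.35, size=n_taxa)
        active = np.argsort(score)[::-1][:m]
        p = np.exp(base_logit[active])
        counts[i, active] = rng.multinomial(depth, p / p.sum())
    taxa = [f"t{j + 1:03d}" for j in range(n_taxa)]
    counts_df = pd.DataFrame(counts, index=pd.Index(visits["sample_id"], name="sample_id"),
                             columns=taxa)
    taxonomy = pd.DataFrame({
        "taxon": taxa,
        "genus": [f"g{j + 1:03d}" for j in range(n_taxa)],
        "family": [f"fam{j // 3 + 1:03d}" for j in range(n_taxa)],
        "order": [f"ord{j // 6 + 1:03d}" for j in range(n_taxa)],
        "class": [f"cls{j // 15 + 1:02d}" for j in range(n_taxa)],
        "phylum": [f"phy{j // 30 + 1:02d}" for j in range(n_taxa)],
    })
    return counts_df, taxonomy
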