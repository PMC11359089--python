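"""Synthetic post-quantification synaptome tables with known ground truth.

The generator emulates the *output* of a whole-brain synaptome-mapping
pipeline — per-animal, per-region punctum summaries (density, median
intensity, median size for PSD95 and SAP102), 37-subtype density
matrices, a subtype -> PSD95-lifetime table, and hippocampal spatial
size profiles — for a four-group design (ZT6, ZT6SD, ZT11, ZT23).  It
never touches images: its purpose is to give every downstream stage a
cohort whose true effects are known exactly.

The injected study conditions mirror the sleep-deprivation phenotype:

* circadian groups (ZT6, ZT11, ZT23) are drawn from identical
  distributions (null by construction);
* the sleep-deprived group (ZT6SD) carries a standardized reduction of
  PSD95 median punctum size confined to cortical (CTX) and hippocampal-
  formation (HPF) regions, calibrated so the expected Cohen's d equals
  ``size_effect_d`` (default -1.0);
* subtype densities in CTX/HPF shift linearly in PSD95-lifetime
  percentile (long-lifetime subtypes up, short-lifetime down) with the
  shifts re-centred to sum to zero, so total synapse density is
  conserved;
* all strictly positive quantities carry multiplicative log-normal
  noise with a fixed coefficient of variation (default 0.15).

Region baselines and per-area subtype proportions are fixed documented
constants (independent of the cohort seed), so two cohorts differ only
through sampling noise and the injected effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "AREAS",
    "GROUPS",
    "DEFAULT_AREA_COUNTS",
    "N_SUBTYPES",
    "N_PSD95_SUBTYPES",
    "LPL_IDS",
    "SPL_IDS",
    "SAP102_ONLY_IDS",
    "CatalogConfig",
    "CohortDesign",
    "EffectSpec",
    "CohortData",
    "SpatialSizeProfiles",
    "make_region_catalog",
    "make_lifetime_table",
    "simulate_cohort",
    "simulate_spatial_profiles",
]

AREAS = ("CTX", "OLF", "HPF", "CTXsp", "STR", "TH", "HY")
GROUPS = ("ZT6", "ZT6SD", "ZT11", "ZT23")
AFFECTED_AREAS = ("CTX", "HPF")

#: Default per-area region counts (125 regions total; 68 CTX, 23 HPF).
DEFAULT_AREA_COUNTS: dict[str, int] = {
    "CTX": 68, "OLF": 8, "HPF": 23, "CTXsp": 6, "STR": 8, "TH": 8, "HY": 4,
}

N_SUBTYPES = 37
N_PSD95_SUBTYPES = 30  # subtypes with a quantified PSD95 lifetime

#: Published long- and short-protein-lifetime subtype sets (top/bottom 6
#: of the 30 lifetime-ranked PSD95-expressing subtypes).
LPL_IDS = (2, 3, 5, 20, 34, 35)
SPL_IDS = (6, 8, 11, 28, 29, 31)
#: Subtypes expressing SAP102 only; these carry no PSD95 lifetime.
SAP102_ONLY_IDS = (13, 16, 19, 22, 25, 30, 37)

PUNCTA_COLUMNS = [
    "animal_id", "group", "sex", "region_id", "area",
    "psd95_density", "psd95_intensity", "psd95_size",
    "sap102_density", "sap102_intensity", "sap102_size",
]

# Fixed seed for the *baseline landscape* (region multipliers, subtype
# proportions); deliberately decoupled from cohort seeds so the
# underlying brain is the same across simulated cohorts.
_BASELINE_SEED = 713_209

# Mean punctum summaries per area: density (puncta/um^2), median
# intensity (a.u.), median size (um^2); plus total subtype density and
# the Dirichlet concentration controlling subtype evenness (CTX/HPF are
# rich and even, subcortical areas sparse and uneven, echoing the known
# diversity gradient).
_AREA_BASELINES: dict[str, dict[str, float]] = {
    "CTX":   dict(psd95_density=0.60, psd95_intensity=120.0, psd95_size=0.28,
                  sap102_density=0.35, sap102_intensity=90.0, sap102_size=0.22,
                  subtype_total=0.75, subtype_alpha=5.0),
    "HPF":   dict(psd95_density=0.55, psd95_intensity=110.0, psd95_size=0.26,
                  sap102_density=0.33, sap102_intensity=85.0, sap102_size=0.21,
                  subtype_total=0.70, subtype_alpha=5.0),
    "OLF":   dict(psd95_density=0.40, psd95_intensity=95.0, psd95_size=0.22,
                  sap102_density=0.28, sap102_intensity=75.0, sap102_size=0.18,
                  subtype_total=0.50, subtype_alpha=1.2),
    "CTXsp": dict(psd95_density=0.38, psd95_intensity=90.0, psd95_size=0.21,
                  sap102_density=0.26, sap102_intensity=70.0, sap102_size=0.18,
                  subtype_total=0.48, subtype_alpha=1.0),
    "STR":   dict(psd95_density=0.35, psd95_intensity=85.0, psd95_size=0.20,
                  sap102_density=0.24, sap102_intensity=68.0, sap102_size=0.17,
                  subtype_total=0.45, subtype_alpha=0.8),
    "TH":    dict(psd95_density=0.30, psd95_intensity=80.0, psd95_size=0.19,
                  sap102_density=0.22, sap102_intensity=65.0, sap102_size=0.16,
                  subtype_total=0.40, subtype_alpha=0.8),
    "HY":    dict(psd95_density=0.28, psd95_intensity=75.0, psd95_size=0.18,
                  sap102_density=0.20, sap102_intensity=60.0, sap102_size=0.15,
                  subtype_total=0.38, subtype_alpha=0.7),
}


@dataclass(frozen=True)
class CatalogConfig:
    """Per-area region counts; defaults give the 125-region atlas layout."""

    area_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AREA_COUNTS))
    total: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.area_counts) - set(AREAS)
        if unknown:
            raise ValueError(f"unknown areas: {sorted(unknown)}")
        counts_sum = sum(self.area_counts.values())
        if self.total is not None and self.total != counts_sum:
            raise ValueError(
                f"area counts sum to {counts_sum}, expected total {self.total}")
        if self.area_counts.get("HPF", 0) < 1:
            raise ValueError("catalog needs at least one HPF region (CA1sr)")


@dataclass(frozen=True)
class CohortDesign:
    """Group sizes and master seed; defaults: ZT6 n=8, other groups n=10."""

    groups: Mapping[str, int] = field(
        default_factory=lambda: {"ZT6": 8, "ZT6SD": 10, "ZT11": 10, "ZT23": 10})
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g} needs n >= 2 animals, got {n}")


@dataclass(frozen=True)
class EffectSpec:
    """Injected ground-truth effects.

    ``size_effect_d``: target standardized PSD95-size reduction in
    CTX/HPF for the sleep-deprived group.  ``subtype_shift_slope``:
    fractional density shift at the extremes of the lifetime-percentile
    scale (zero-sum within each region).  ``noise_cv``: log-normal
    coefficient of variation of every positive measurement.
    """

    size_effect_d: float = -1.0
    subtype_shift_slope: float = 0.3
    noise_cv: float = 0.15
    circadian_null: bool = True

    def __post_init__(self) -> None:
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if not self.circadian_null:
            raise ValueError(
                "circadian effects are not modeled; circadian_null must stay True")


@dataclass(frozen=True)
class CohortData:
    puncta: pd.DataFrame
    subtypes: pd.DataFrame
    ground_truth: dict


@dataclass(frozen=True)
class SpatialSizeProfiles:
    """Hippocampal size profiles: per group x protein 4x4 geometric-mean
    matrices (tangential subregions CA1/CA2/CA3/DG x radial layers) and
    per-protein 11x11 CA1sr baseline profiles in (0, 1]."""

    group_matrices: dict[str, dict[str, np.ndarray]]
    baselines: dict[str, np.ndarray]

    def to_json(self) -> str:
        payload = {
            "group_matrices": {
                g: {p: np.asarray(m).tolist() for p, m in prots.items()}
                for g, prots in self.group_matrices.items()
            },
            "baselines": {p: np.asarray(m).tolist() for p, m in self.baselines.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SpatialSizeProfiles":
        payload = json.loads(text)
        return cls(
            group_matrices={
                g: {p: np.asarray(m, dtype=float) for p, m in prots.items()}
                for g, prots in payload["group_matrices"].items()
            },
            baselines={p: np.asarray(m, dtype=float)
                       for p, m in payload["baselines"].items()},
        )


def make_region_catalog(config: CatalogConfig | None = None) -> pd.DataFrame:
    """Deterministic region catalog: region_id, area, is_ca1sr.

    The first HPF region is flagged as CA1 stratum radiatum (CA1sr),
    the layer driving the physiology model.
    """
    config = config or CatalogConfig()
    rows = []
    for area in AREAS:
        n = config.area_counts.get(area, 0)
        for i in range(1, n + 1):
            if area == "HPF" and i == 1:
                rows.append({"region_id": "HPF-CA1sr", "area": area, "is_ca1sr": True})
            else:
                rows.append({"region_id": f"{area}-{i:03d}", "area": area,
                             "is_ca1sr": False})
    catalog = pd.DataFrame(rows, columns=["region_id", "area", "is_ca1sr"])
    if catalog["region_id"].duplicated().any():
        raise ValueError("region ids are not unique")
    return catalog


def make_lifetime_table(seed: int = 0) -> pd.DataFrame:
    """Subtype catalog with strictly ranked PSD95 lifetime percentiles.

    All 37 subtypes are listed; the 30 PSD95-expressing ones receive
    distinct lifetime percentiles in [0, 100] such that the published
    LPL ids hold the six longest lifetimes and the SPL ids the six
    shortest.  SAP102-only subtypes carry no lifetime.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11F37]))
    psd95_ids = [i for i in range(1, N_SUBTYPES + 1) if i not in SAP102_ONLY_IDS]
    middle_ids = [i for i in psd95_ids if i not in LPL_IDS and i not in SPL_IDS]

    def block(lo: float, hi: float, k: int) -> np.ndarray:
        # evenly spread with jitter < half the gap, so values stay distinct
        base = np.linspace(lo, hi, k)
        gap = (hi - lo) / max(k - 1, 1)
        return base + rng.uniform(-0.4, 0.4, k) * gap

    spl_vals = np.sort(block(2.0, 20.0, len(SPL_IDS)))
    mid_vals = np.sort(block(25.0, 75.0, len(middle_ids)))
    lpl_vals = np.sort(block(80.0, 98.0, len(LPL_IDS)))

    lifetime: dict[int, float] = {}
    for ids, vals in ((SPL_IDS, spl_vals), (middle_ids, mid_vals), (LPL_IDS, lpl_vals)):
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            lifetime[list(ids)[idx]] = float(vals[rank])

    rows = []
    for sid in range(1, N_SUBTYPES + 1):
        if sid in SAP102_ONLY_IDS:
            stype, pct = "SAP102_only", np.nan
        else:
            stype = "colocalized" if sid % 2 == 0 else "PSD95_only"
            pct = lifetime[sid]
        rows.append({"subtype_id": sid, "type": stype, "lifetime_pct": pct})
    return pd.DataFrame(rows, columns=["subtype_id", "type", "lifetime_pct"])


# ---------------------------------------------------------------------------
# Baseline landscape (fixed constants derived from _BASELINE_SEED)
# ---------------------------------------------------------------------------

def _region_multipliers(catalog: pd.DataFrame) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([_BASELINE_SEED, 1]))
    return rng.uniform(0.8, 1.2, len(catalog))


def _area_subtype_proportions() -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([_BASELINE_SEED, 2]))
    out = {}
    for area in AREAS:
        alpha = _AREA_BASELINES[area]["subtype_alpha"]
        out[area] = rng.dirichlet(np.full(N_SUBTYPES, alpha))
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    s2 = math.log(1.0 + cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size))


def _size_multiplier(d: float, cv: float, n_sd: int, n_ctrl: int) -> float:
    """Multiplier r on the SD-group mean so the expected Cohen's d is ``d``.

    With group SDs proportional to the means (constant CV), the pooled
    SD depends on r; solve r = 1 + d*cv*sqrt(((n1-1) r^2 + (n2-1)) /
    (n1+n2-2)) by fixed-point iteration (contraction for |d*cv| < 1).
    """
    if d == 0:
        return 1.0
    df = n_sd + n_ctrl - 2
    r = 1.0
    for _ in range(50):
        r_new = 1.0 + d * cv * math.sqrt(((n_sd - 1) * r * r + (n_ctrl - 1)) / df)
        if abs(r_new - r) < 1e-14:
            r = r_new
            break
        r = r_new
    if r <= 0:
        raise ValueError("size effect too large for the given CV (non-positive mean)")
    return r


def simulate_cohort(
    catalog: pd.DataFrame,
    design: CohortDesign,
    effects: EffectSpec,
    lifetimes: pd.DataFrame,
) -> CohortData:
    """Simulate punctum-summary and subtype-density tables for one cohort.

    Returns tidy tables (one row per animal x region) plus a ground-truth
    record of every injected effect.  Identical designs and seeds give
    byte-identical tables.
    """
    cv = effects.noise_cv
    ss = np.random.SeedSequence([design.seed, 0xC0F0])
    rng_meta, rng_puncta, rng_subtype = (
        np.random.default_rng(s) for s in ss.spawn(3))

    region_mult = _region_multipliers(catalog)
    proportions = _area_subtype_proportions()
    affected = catalog["area"].isin(AFFECTED_AREAS).to_numpy()

    n_sd = design.groups.get("ZT6SD", 0)
    n_ctrl = design.groups.get("ZT6", 0)
    r_size = (_size_multiplier(effects.size_effect_d, cv, n_sd, n_ctrl)
              if (n_sd >= 2 and n_ctrl >= 2) else 1.0)

    # lifetime weights in [-1, 1] for the 30 PSD95-expressing subtypes
    lt = lifetimes.set_index("subtype_id")["lifetime_pct"]
    weights = np.zeros(N_SUBTYPES)
    has_lifetime = np.zeros(N_SUBTYPES, dtype=bool)
    for sid in range(1, N_SUBTYPES + 1):
        pct = lt.get(sid, np.nan)
        if np.isfinite(pct):
            weights[sid - 1] = (pct - 50.0) / 50.0
            has_lifetime[sid - 1] = True

    animals = []
    for group in GROUPS:
        n = design.groups.get(group, 0)
        sexes = rng_meta.permutation(["M", "F"] * ((n + 1) // 2))[:n]
        for i in range(n):
            animals.append((f"{group}-{i + 1:02d}", group, str(sexes[i])))

    n_regions = len(catalog)
    areas = catalog["area"].to_numpy()
    region_ids = catalog["region_id"].to_numpy()

    puncta_rows = []
    subtype_rows = []
    params = ("psd95_density", "psd95_intensity", "psd95_size",
              "sap102_density", "sap102_intensity", "sap102_size")
    for animal_id, group, sex in animals:
        noise = _lognormal_factor(rng_puncta, cv, (n_regions, len(params)))
        sub_noise = _lognormal_factor(rng_subtype, cv, (n_regions, N_SUBTYPES))
        for j in range(n_regions):
            area = areas[j]
            base = _AREA_BASELINES[area]
            row = {"animal_id": animal_id, "group": group, "sex": sex,
                   "region_id": region_ids[j], "area": area}
            for k, p in enumerate(params):
                expected = base[p] * region_mult[j]
                if p == "psd95_size" and group == "ZT6SD" and affected[j]:
                    expected *= r_size
                row[p] = expected * noise[j, k]
            puncta_rows.append(row)

            total = base["subtype_total"] * region_mult[j]
            expected_sub = total * proportions[area]
            if group == "ZT6SD" and affected[j] and effects.subtype_shift_slope != 0:
                shift = effects.subtype_shift_slope * weights * expected_sub
                shift[has_lifetime] -= shift.sum() / has_lifetime.sum()
                shift[~has_lifetime] = 0.0
                expected_sub = expected_sub + shift
                if np.any(expected_sub <= 0):
                    raise ValueError(
                        "subtype shift slope too large: negative expected density")
            srow = {"animal_id": animal_id, "group": group,
                    "region_id": region_ids[j]}
            vals = expected_sub * sub_noise[j]
            for sid in range(1, N_SUBTYPES + 1):
                srow[f"subtype_{sid}"] = vals[sid - 1]
            subtype_rows.append(srow)

    puncta = pd.DataFrame(puncta_rows, columns=PUNCTA_COLUMNS)
    subtype_cols = (["animal_id", "group", "region_id"]
                    + [f"subtype_{i}" for i in range(1, N_SUBTYPES + 1)])
    subtypes = pd.DataFrame(subtype_rows, columns=subtype_cols)

    ground_truth = {
        "seed": design.seed,
        "groups": dict(design.groups),
        "noise_cv": cv,
        "size_effect_d": effects.size_effect_d,
        "psd95_size_multiplier": r_size,
        "subtype_shift_slope": effects.subtype_shift_slope,
        "affected_areas": list(AFFECTED_AREAS),
        "affected_regions": [str(r) for r in region_ids[affected]],
        "circadian_null": effects.circadian_null,
    }
    return CohortData(puncta=puncta, subtypes=subtypes, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# Spatial size profiles for the physiology model
# ---------------------------------------------------------------------------

# Fixed 4x4 mean-size surfaces (um^2): rows CA1, CA2, CA3, DG; columns
# the four radial layers.  Gentle monotone gradients along both axes.
_TANGENTIAL_RAMP = np.array([1.00, 0.92, 0.86, 0.78])
_RADIAL_RAMP = np.array([1.00, 0.90, 0.82, 0.76])
_PROTEIN_BASE_SIZE = {"psd95": 0.28, "sap102": 0.22}


def _mean_size_matrix(protein: str) -> np.ndarray:
    return _PROTEIN_BASE_SIZE[protein] * np.outer(_TANGENTIAL_RAMP, _RADIAL_RAMP)


def _ca1sr_baseline(protein: str) -> np.ndarray:
    """Fixed 11x11 CA1sr scale-factor baseline in (0, 1]."""
    lin = np.linspace(0.0, 1.0, 11)
    if protein == "psd95":
        prof = 0.45 + 0.50 * np.outer(1.0 - 0.6 * lin, 1.0 - 0.5 * lin)
    else:
        prof = 0.40 + 0.55 * np.outer(1.0 - 0.4 * lin, 1.0 - 0.7 * lin)
    return np.clip(prof, 1e-6, 1.0)


def simulate_spatial_profiles(
    design: CohortDesign,
    effects: EffectSpec,
    seed: int | None = None,
) -> SpatialSizeProfiles:
    """Per-group geometric-mean 4x4 size matrices plus CA1sr baselines.

    Per-animal matrices are drawn with the cohort's log-normal noise and
    aggregated by the geometric mean over individuals; the sleep-deprived
    group's PSD95 matrix is scaled down per ``size_effect_d`` (same
    multiplier as the punctum-size effect), shrinking its directional
    spans relative to control.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57A7]))
    cv = effects.noise_cv
    n_sd = design.groups.get("ZT6SD", 0)
    n_ctrl = design.groups.get("ZT6", 0)
    r_size = (_size_multiplier(effects.size_effect_d, cv, n_sd, n_ctrl)
              if (n_sd >= 2 and n_ctrl >= 2) else 1.0)

    group_matrices: dict[str, dict[str, np.ndarray]] = {}
    for group in GROUPS:
        n = design.groups.get(group, 0)
        if n == 0:
            continue
        group_matrices[group] = {}
        for protein in ("psd95", "sap102"):
            expected = _mean_size_matrix(protein)
            if protein == "psd95" and group == "ZT6SD":
                expected = expected * r_size
            per_animal = expected[None, :, :] * _lognormal_factor(
                rng, cv, (n, 4, 4))
            group_matrices[group][protein] = gmean(per_animal, axis=0)

    baselines = {p: _ca1sr_baseline(p) for p in ("psd95", "sap102")}
    return SpatialSizeProfiles(group_matrices=group_matrices, baselines=baselines)
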