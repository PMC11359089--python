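"""End-to-end orchestration: simulate -> effect maps -> contrasts -> physiology.

A run is fully determined by its :class:`RunConfig`.  The stages mirror
the analysis narrative of the sleep-deprivation synaptome study:
circadian null check (ZT6 vs ZT11 and ZT23), sleep-deprivation size and
diversity maps, the lifetime-ranked LPL-vs-SPL subtype contrast, and the
CA1sr activity-pattern battery.  Every artifact is a plain TSV or JSON
file; the report records paths, SHA-256 checksums and headline counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import physiology, stats, synth

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "RunReport",
    "read_table",
    "write_table",
    "run_full_analysis",
]

log = logging.getLogger("synaptome_sd")

#: Required column order per table kind (extra columns are rejected).
SCHEMAS: dict[str, list[str]] = {
    "puncta": list(synth.PUNCTA_COLUMNS),
    "subtypes": (["animal_id", "group", "region_id"]
                 + [f"subtype_{i}" for i in range(1, synth.N_SUBTYPES + 1)]),
    "lifetimes": ["subtype_id", "type", "lifetime_pct"],
    "effect_map": list(stats.EFFECT_MAP_COLUMNS),
    "battery": ["pattern", "ed_spatial", "ed_intensity", "ks_stat", "ks_p",
                "ks_p_adj", "cohens_d", "n"],
    "fit_targets": ["kind", "index", "value"],
}


def write_table(table: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a TSV with the fixed column order of ``schema`` (full precision)."""
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in table.columns]
    extra = [c for c in table.columns if c not in cols]
    if missing or extra:
        raise ValueError(
            f"schema {schema!r} mismatch: missing={missing} unexpected={extra}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, validating its columns."""
    table = pd.read_csv(path, sep="\t")
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in table.columns]
    extra = [c for c in table.columns if c not in cols]
    if missing or extra:
        raise ValueError(
            f"schema {schema!r} mismatch in {path}: missing={missing} "
            f"unexpected={extra}")
    return table[cols]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one analysis run."""

    seed: int = 0
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"ZT6": 8, "ZT6SD": 10, "ZT11": 10, "ZT23": 10})
    size_effect_d: float = -1.0
    subtype_shift_slope: float = 0.3
    noise_cv: float = 0.15
    n_draws: int = 2000
    alpha: float = 0.05
    patterns: Sequence[str] = physiology.PATTERN_NAMES
    out_dir: str = "synaptome_sd_run"

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def effects(self) -> synth.EffectSpec:
        return synth.EffectSpec(
            size_effect_d=self.size_effect_d,
            subtype_shift_slope=self.subtype_shift_slope,
            noise_cv=self.noise_cv,
        )

    def design(self) -> synth.CohortDesign:
        return synth.CohortDesign(groups=dict(self.groups), seed=self.seed)

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["groups"] = dict(self.groups)
        payload["patterns"] = list(self.patterns)
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text)
        return cls(**payload)


@dataclass(frozen=True)
class RunReport:
    config: RunConfig
    files: dict[str, str]
    checksums: dict[str, str]
    summary: dict

    def to_json(self) -> str:
        payload = {
            "config": yaml.safe_load(self.config.to_yaml()),
            "files": self.files,
            "checksums": self.checksums,
            "summary": self.summary,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _significant_by_area(
    effect_map: pd.DataFrame, catalog: pd.DataFrame, alpha: float
) -> dict[str, int]:
    merged = effect_map.merge(catalog[["region_id", "area"]], on="region_id")
    sig = merged[(~merged["excluded"]) & (merged["p_adj"] < alpha)]
    return {area: int((sig["area"] == area).sum()) for area in synth.AREAS}


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the full pipeline; deterministic for a fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    summary: dict = {}

    ss = np.random.SeedSequence([config.seed, 0xF1FE])
    stat_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]

    log.info("stage 1: synthetic cohort (seed=%d)", config.seed)
    catalog = synth.make_region_catalog()
    lifetimes = synth.make_lifetime_table(seed=config.seed)
    cohort = synth.simulate_cohort(
        catalog, config.design(), config.effects(), lifetimes)
    profiles = synth.simulate_spatial_profiles(config.design(), config.effects())
    files["puncta"] = str(write_table(cohort.puncta, out / "puncta.tsv", "puncta"))
    files["subtypes"] = str(
        write_table(cohort.subtypes, out / "subtypes.tsv", "subtypes"))
    files["lifetimes"] = str(
        write_table(lifetimes, out / "lifetimes.tsv", "lifetimes"))
    (out / "profiles.json").write_text(profiles.to_json())
    files["profiles"] = str(out / "profiles.json")
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=1, sort_keys=True))
    files["ground_truth"] = str(out / "ground_truth.json")

    maps = {}
    circadian = [g for g in ("ZT11", "ZT23") if config.groups.get(g, 0) >= 2]
    for i, other in enumerate(circadian):
        log.info("stage 2: circadian null map ZT6 vs %s", other)
        maps[f"circadian_size_{other}"] = stats.region_map_compare(
            cohort.puncta, "ZT6", other, "psd95_size",
            n_draws=config.n_draws, seed=stat_seeds[i])

    log.info("stage 3: sleep-deprivation PSD95 size map")
    maps["sd_size"] = stats.region_map_compare(
        cohort.puncta, "ZT6SD", "ZT6", "psd95_size",
        n_draws=config.n_draws, seed=stat_seeds[2])

    log.info("stage 4: subtype diversity map")
    maps["sd_diversity"] = stats.region_map_compare(
        cohort.subtypes, "ZT6SD", "ZT6", "diversity",
        n_draws=config.n_draws, seed=stat_seeds[3])

    log.info("stage 5: LPL vs SPL contrast")
    maps["lpl_spl"] = stats.lpl_spl_contrast(
        cohort.subtypes, lifetimes, "ZT6SD", "ZT6",
        n_draws=config.n_draws, seed=stat_seeds[4])

    for name, table in maps.items():
        files[name] = str(write_table(table, out / f"{name}.tsv", "effect_map"))
        summary[f"significant_{name}"] = _significant_by_area(
            table, catalog, config.alpha)
        excluded = table["excluded"].sum()
        if excluded:
            log.warning("map %s: %d regions excluded (insufficient animals)",
                        name, excluded)

    log.info("stage 6: CA1sr activity-pattern battery ZT6 vs ZT6SD")
    grid_ctrl = physiology.build_grid(profiles, "ZT6")
    grid_sd = physiology.build_grid(profiles, "ZT6SD")
    battery = physiology.run_pattern_battery(
        grid_sd, grid_ctrl, patterns=config.patterns)
    files["battery"] = str(write_table(battery, out / "battery.tsv", "battery"))
    summary["battery_significant_patterns"] = [
        str(p) for p in battery.loc[battery["ks_p_adj"] < config.alpha, "pattern"]
    ]
    summary["grid_n_synapses"] = grid_ctrl.n_synapses

    (out / "config.yaml").write_text(config.to_yaml())
    files["config"] = str(out / "config.yaml")

    checksums = {name: _sha256(Path(p)) for name, p in sorted(files.items())}
    report = RunReport(config=config, files=files, checksums=checksums,
                       summary=summary)
    (out / "report.json").write_text(report.to_json())
    for name, p in files.items():
        if not Path(p).exists():  # closure guarantee of the report contract
            raise RuntimeError(f"stage output missing: {name} -> {p}")
    return report
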