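"""Synthetic cohort generator emulating a balanced 2x2 (race x disease) design
with log-normal analyte panels, planted group effects, planted analyte
covariance clusters, and planted stratum-specific ratio-endpoint correlations.

Every random draw comes from a per-block substream of the master seed, so
adding analytes or clusters never perturbs previously generated columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clinical
from .cohort import GROUPS, CohortTable
from .errors import ConfigurationError

FACTORS = ("race", "disease", "interaction")
PLANT_STRATA = ("White", "AA", "both")

#: Default correlation loading shared by members of a planted cluster
#: (pairwise within-cluster correlation is its square on the log scale).
DEFAULT_CLUSTER_LOADING = 0.8

#: Cytokine analytes named after a multiplex inflammation panel; synthetic
#: CK.xx fillers complete the requested count.
CYTOKINE_NAMES = [
    "IL-17A", "IL-17E", "IL-17F", "IL-21", "IL-22", "IL-6", "TNF-a", "IL-1b",
    "MCP-1", "eotaxin", "IL-27", "IL-12p70", "sCD40L", "RANTES", "G-CSF",
    "IFN-g", "IL-33", "MIP-3a",
]

LIPID_CLASSES = [
    ("TG", 0.35), ("PC", 0.14), ("PE", 0.10), ("DG", 0.10),
    ("SM", 0.10), ("CE", 0.08), ("Cer", 0.07), ("Sph", 0.06),
]

#: Clinical markers: (baseline level, log-scale SD).  LDL and VLDL are derived.
CLINICAL_SPEC = {
    "clin_chol": (190.0, 0.15),
    "clin_hdl": (50.0, 0.25),
    "clin_triglycerides": (120.0, 0.40),
    "clin_hba1c": (5.4, 0.08),
    "clin_insulin": (10.0, 0.50),
    "clin_glucose": (95.0, 0.12),
    "clin_hs_crp": (2.0, 0.80),
    "clin_whr": (0.95, 0.08),
}

# covariate ranges mirroring the reference demographics table
BMI_RANGE = (20.57, 41.28)
AGE_RANGE = (30.0, 64.8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    cluster_id: int
    n_members: int
    group_shifts: dict = field(default_factory=dict)  # group label -> z-shift


@dataclass
class EffectSpec:
    analyte: str
    factor: str          # race | disease | interaction
    size: float          # in per-analyte log-scale SD units


@dataclass
class RatioPlantSpec:
    lipid: str
    cytokine: str
    stratum: str         # White | AA | both
    r: float             # target in-stratum correlation with HbA1C (log scale)


def default_lipid_clusters() -> list[ClusterSpec]:
    return [
        ClusterSpec(1, 15, {"NoDx-White": 0.8, "Dx-White": 0.8, "NoDx-AA": -0.8, "Dx-AA": -0.8}),
        ClusterSpec(2, 12, {"NoDx-White": -0.8, "Dx-White": 0.8, "NoDx-AA": -0.8, "Dx-AA": 0.8}),
        ClusterSpec(3, 11, {"NoDx-White": -0.4, "Dx-White": 1.2, "NoDx-AA": -0.4, "Dx-AA": -0.4}),
    ]


def default_cytokine_clusters() -> list[ClusterSpec]:
    shifts = [
        {"NoDx-White": 0.5, "Dx-White": 0.5, "NoDx-AA": -0.5, "Dx-AA": -0.5},
        {"NoDx-White": -0.5, "Dx-White": 0.5, "NoDx-AA": -0.5, "Dx-AA": 0.5},
        {"NoDx-White": 0.0, "Dx-White": 0.0, "NoDx-AA": 0.0, "Dx-AA": 0.0},
        {"NoDx-White": -0.3, "Dx-White": 1.0, "NoDx-AA": -0.3, "Dx-AA": -0.4},
        {"NoDx-White": 0.0, "Dx-White": 0.0, "NoDx-AA": 0.0, "Dx-AA": 0.0},
        {"NoDx-White": -0.3, "Dx-White": -0.3, "NoDx-AA": 0.3, "Dx-AA": 0.3},
    ]
    return [ClusterSpec(i + 1, 4, s) for i, s in enumerate(shifts)]


def default_effects() -> list[EffectSpec]:
    return [
        EffectSpec("clin_hba1c", "disease", 2.0),
        EffectSpec("clin_glucose", "disease", 2.0),
        EffectSpec("clin_insulin", "disease", 1.0),
        EffectSpec("clin_insulin", "race", 0.8),
        EffectSpec("clin_hs_crp", "disease", 0.8),
        EffectSpec("clin_hs_crp", "interaction", 1.5),
        EffectSpec("clin_triglycerides", "disease", 0.8),
    ]


@dataclass
class GeneratorConfig:
    n_per_group: int = 10
    n_lipids: int = 128
    n_cytokines: int = 47
    lipid_cluster_spec: list = field(default_factory=default_lipid_clusters)
    cytokine_cluster_spec: list = field(default_factory=default_cytokine_clusters)
    effect_table: list = field(default_factory=default_effects)
    ratio_plant_spec: list = field(default_factory=list)
    noise_sd: float = 1.0
    cluster_loading: float = DEFAULT_CLUSTER_LOADING
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_per_group % 2:
            raise ConfigurationError("n_per_group must be even for exact 50/50 sex balance")
        if self.n_lipids < 1 or self.n_cytokines < 1:
            raise ConfigurationError("panel sizes must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.cluster_loading < 1.0:
            raise ConfigurationError("cluster_loading must be in [0, 1)")
        for spec_list, n_max, label in (
            (self.lipid_cluster_spec, self.n_lipids, "lipid"),
            (self.cytokine_cluster_spec, self.n_cytokines, "cytokine"),
        ):
            total = sum(s.n_members for s in spec_list)
            if total > n_max:
                raise ConfigurationError(
                    f"{label} cluster members ({total}) exceed panel size ({n_max})"
                )
            ids = [s.cluster_id for s in spec_list]
            if len(ids) != len(set(ids)):
                raise ConfigurationError(f"duplicate {label} cluster ids")
        for e in self.effect_table:
            if e.factor not in FACTORS:
                raise ConfigurationError(f"unknown factor {e.factor!r} for {e.analyte}")
        for plant in self.ratio_plant_spec:
            if plant.stratum not in PLANT_STRATA:
                raise ConfigurationError(f"unknown stratum {plant.stratum!r}")
            if not -1.0 < plant.r < 1.0:
                raise ConfigurationError(
                    f"target correlation must be in (-1, 1), got {plant.r}"
                )

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["lipid_cluster_spec"] = [ClusterSpec(**s) for s in d.get("lipid_cluster_spec", [])]
        d["cytokine_cluster_spec"] = [ClusterSpec(**s) for s in d.get("cytokine_cluster_spec", [])]
        d["effect_table"] = [EffectSpec(**s) for s in d.get("effect_table", [])]
        d["ratio_plant_spec"] = [RatioPlantSpec(**s) for s in d.get("ratio_plant_spec", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TruthManifest:
    planted_effects: list
    planted_clusters: dict                 # analyte -> "lipid:1" style cluster tag
    planted_ratio_correlations: list       # (lipid, cytokine, stratum, target r, realized r)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_effects": [dataclasses.asdict(e) for e in self.planted_effects],
            "planted_clusters": self.planted_clusters,
            "planted_ratio_correlations": [
                {"lipid": l, "cytokine": c, "stratum": s, "target_r": t, "realized_r": r}
                for (l, c, s, t, r) in self.planted_ratio_correlations
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def lipid_names(n: int) -> list[str]:
    """Class-prefixed synthetic species names (e.g. ``lip_TG.48.2``)."""
    counts = [int(np.floor(w * n)) for _, w in LIPID_CLASSES]
    i = 0
    while sum(counts) < n:
        counts[i % len(counts)] += 1
        i += 1
    names = []
    for (cls, _), c in zip(LIPID_CLASSES, counts):
        for j in range(c):
            names.append(f"lip_{cls}.{40 + 2 * j}.{j % 7}")
    return names[:n]


def cytokine_names(n: int) -> list[str]:
    base = [f"cyt_{name}" for name in CYTOKINE_NAMES[:n]]
    extra = [f"cyt_CK.{i:02d}" for i in range(len(base), n)]
    return base + extra


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _rng(seed: int, block: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(block, index)))


def _rng_named(seed: int, block: int, name: str) -> np.random.Generator:
    """Substream keyed by a stable digest of the analyte name, so growing a
    panel never perturbs the values of analytes that already existed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(block, key)))


def _factor_offset(effect: EffectSpec, race_sign: np.ndarray, dis_sign: np.ndarray) -> np.ndarray:
    """Cell-mean offsets so main-effect differences / the interaction contrast
    equal the requested size (AA minus White; Dx minus NoDx)."""
    if effect.factor == "race":
        return effect.size / 2.0 * race_sign
    if effect.factor == "disease":
        return effect.size / 2.0 * dis_sign
    return effect.size / 4.0 * race_sign * dis_sign


def _panel_values(
    cfg: GeneratorConfig,
    names: Sequence[str],
    cluster_spec: Sequence[ClusterSpec],
    group: np.ndarray,
    race_sign: np.ndarray,
    dis_sign: np.ndarray,
    effects: dict[str, list[EffectSpec]],
    factor_block: int,
    noise_block: int,
) -> tuple[pd.DataFrame, dict[str, int]]:
    n = group.size
    latent = {
        s.cluster_id: _rng(cfg.seed, factor_block, s.cluster_id).standard_normal(n)
        for s in cluster_spec
    }
    membership: dict[str, int] = {}
    cursor = 0
    for s in cluster_spec:
        for name in names[cursor:cursor + s.n_members]:
            membership[name] = s.cluster_id
        cursor += s.n_members
    spec_by_id = {s.cluster_id: s for s in cluster_spec}

    cols = {}
    for name in names:
        rng = _rng_named(cfg.seed, noise_block, name)
        baseline = rng.uniform(np.log(10.0), np.log(1000.0))
        eps = rng.standard_normal(n)
        z = np.zeros(n)
        if name in membership:
            s = spec_by_id[membership[name]]
            shifts = np.array([s.group_shifts.get(g, 0.0) for g in group])
            z = shifts + cfg.cluster_loading * latent[s.cluster_id]
            z = z + np.sqrt(1.0 - cfg.cluster_loading ** 2) * eps
        else:
            z = eps
        for e in effects.get(name, []):
            z = z + _factor_offset(e, race_sign, dis_sign)
        cols[name] = np.exp(baseline + cfg.noise_sd * z)
    return pd.DataFrame(cols), membership


def _planted_hba1c_noise(
    cfg: GeneratorConfig,
    eps: np.ndarray,
    race: np.ndarray,
    log_lipids: pd.DataFrame,
    log_cytokines: pd.DataFrame,
) -> np.ndarray:
    """Replace the HbA1C noise inside planted strata with a component carrying
    the requested log-ratio correlations (exact in-sample, by construction)."""
    h = eps.copy()
    for stratum in ("White", "AA"):
        plants = [p for p in cfg.ratio_plant_spec if p.stratum in (stratum, "both")]
        if not plants:
            continue
        rows = race == stratum
        m = int(rows.sum())
        us = []
        for p in plants:
            u = (log_lipids.loc[rows, p.lipid] - log_cytokines.loc[rows, p.cytokine]).to_numpy()
            u = (u - u.mean()) / u.std(ddof=0)
            us.append(u)
        U = np.column_stack(us)
        rs = np.array([p.r for p in plants])
        if float(rs @ rs) >= 1.0:
            raise ConfigurationError("sum of squared planted correlations must be < 1")
        e = eps[rows]
        # residualize the noise against the planted directions, then standardize
        coef, *_ = np.linalg.lstsq(U, e, rcond=None)
        e_perp = e - U @ coef
        sd = e_perp.std(ddof=0)
        if sd == 0:
            e_perp = np.zeros(m)
        else:
            e_perp = (e_perp - e_perp.mean()) / sd
        h[rows] = U @ rs + np.sqrt(max(1.0 - float(rs @ rs), 0.0)) * e_perp
    return h


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, TruthManifest]:
    """Emit a balanced synthetic cohort plus the ground-truth manifest."""
    cfg = config
    cfg.validate()
    n = cfg.n_per_group
    n_total = 4 * n

    lip_names = lipid_names(cfg.n_lipids)
    cyt_names = cytokine_names(cfg.n_cytokines)
    known = set(lip_names) | set(cyt_names) | set(CLINICAL_SPEC)
    for e in cfg.effect_table:
        if e.analyte not in known:
            raise ConfigurationError(f"effect references unknown analyte {e.analyte!r}")
    for p in cfg.ratio_plant_spec:
        if p.lipid not in lip_names:
            raise ConfigurationError(f"ratio plant references unknown lipid {p.lipid!r}")
        if p.cytokine not in cyt_names:
            raise ConfigurationError(f"ratio plant references unknown cytokine {p.cytokine!r}")

    # --- design --------------------------------------------------------
    group = np.repeat(GROUPS, n)
    disease = np.array([g.split("-", 1)[0] for g in group])
    race = np.array([g.split("-", 1)[1] for g in group])
    race_sign = np.where(race == "AA", 1.0, -1.0)
    dis_sign = np.where(disease == "Dx", 1.0, -1.0)
    sex = np.tile(np.array(["F", "M"]), n_total // 2)

    rng_cov = _rng(cfg.seed, 0)
    bmi = rng_cov.uniform(*BMI_RANGE, size=n_total)
    age = rng_cov.uniform(*AGE_RANGE, size=n_total)
    poverty = np.where(rng_cov.random(n_total) < 0.2, "below", "above")
    statin_use = (rng_cov.random(n_total) < 0.3).astype(int)
    insulin_use = ((disease == "Dx") & (rng_cov.random(n_total) < 0.2)).astype(int)

    effects: dict[str, list[EffectSpec]] = {}
    for e in cfg.effect_table:
        effects.setdefault(e.analyte, []).append(e)

    # --- analyte panels ------------------------------------------------
    lipids, lip_membership = _panel_values(
        cfg, lip_names, cfg.lipid_cluster_spec, group, race_sign, dis_sign,
        effects, factor_block=2, noise_block=3,
    )
    cytokines, cyt_membership = _panel_values(
        cfg, cyt_names, cfg.cytokine_cluster_spec, group, race_sign, dis_sign,
        effects, factor_block=4, noise_block=5,
    )

    # --- clinical panel -------------------------------------------------
    clin = {}
    for marker, (baseline, log_sd) in CLINICAL_SPEC.items():
        rng = _rng_named(cfg.seed, 1, marker)
        eps = rng.standard_normal(n_total)
        offset = np.zeros(n_total)
        for e in effects.get(marker, []):
            offset = offset + _factor_offset(e, race_sign, dis_sign)
        if marker == "clin_hba1c" and cfg.ratio_plant_spec:
            eps = _planted_hba1c_noise(cfg, eps, race, np.log(lipids), np.log(cytokines))
        clin[marker] = baseline * np.exp(log_sd * (offset + eps))
    clin["clin_vldl"] = clin["clin_triglycerides"] / 5.0
    clin["clin_ldl"] = np.clip(clin["clin_chol"] - clin["clin_hdl"] - clin["clin_vldl"], 5.0, None)

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i+1:03d}" for i in range(n_total)],
            "race": race,
            "disease": disease,
            "sex": sex,
            "bmi": bmi,
            "age": age,
            "poverty": poverty,
            "statin_use": statin_use,
            "insulin_use": insulin_use,
        }
    )
    frame = pd.concat([frame, pd.DataFrame(clin), lipids, cytokines], axis=1)
    frame = clinical.add_derived_columns(frame)
    cohort = CohortTable(frame)

    # --- manifest -------------------------------------------------------
    planted_clusters = {a: f"lipid:{c}" for a, c in lip_membership.items()}
    planted_clusters.update({a: f"cytokine:{c}" for a, c in cyt_membership.items()})
    realized = []
    for p in cfg.ratio_plant_spec:
        for stratum in (("White", "AA") if p.stratum == "both" else (p.stratum,)):
            rows = race == stratum
            ratio = (lipids.loc[rows, p.lipid] / cytokines.loc[rows, p.cytokine]).to_numpy()
            hb = np.asarray(clin["clin_hba1c"])[rows]
            realized_r = float(np.corrcoef(ratio, hb)[0, 1])
            realized.append((p.lipid, p.cytokine, stratum, p.r, realized_r))

    manifest = TruthManifest(
        planted_effects=list(cfg.effect_table),
        planted_clusters=planted_clusters,
        planted_ratio_correlations=realized,
    )
    return cohort, manifest
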