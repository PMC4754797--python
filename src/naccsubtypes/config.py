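"""Pipeline configuration and output-table validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic_data as sdata

__all__ = ["PipelineConfig", "load_config", "validate_tables"]

#: default symptom shifts tied to the right-ROI subtypes: both the
#: hyperactive and the suppressed profile carry heavier suicidal-ideation
#: and anhedonia scores than the intermediate profile.
DEFAULT_SYMPTOM_EFFECTS: dict[tuple[str, str], float] = {
    ("Suicidal ideation (HAM-D)", "hyperactive"): 1.5,
    ("Suicidal ideation (HAM-D)", "suppressed"): 1.5,
    (
        "I would enjoy looking smart when I have made an effort with my appearance (SHAPS)",
        "hyperactive",
    ): 1.0,
    (
        "I would enjoy looking smart when I have made an effort with my appearance (SHAPS)",
        "suppressed",
    ): 1.0,
}


@dataclass
class GlmConfig:
    tr: float = 2.0
    n_vols: int = 272
    drop_initial: int = 5
    n_sessions: int = 2
    trials_per_condition: int = 15


@dataclass
class ClusteringConfig:
    k_max: int = 8
    alpha: float = 0.05


@dataclass
class SdaConfig:
    min_variables: int = 1
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    generator: sdata.GeneratorConfig = field(default_factory=sdata.GeneratorConfig)
    glm: GlmConfig = field(default_factory=GlmConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    sda: SdaConfig = field(default_factory=SdaConfig)
    output_dir: str = "pipeline_out"
    seed: int = 0
    run_glm: bool = True

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # location is not scientific config
        payload["generator"]["symptom_effects"] = sorted(
            (k[0], k[1], v) for k, v in (self.generator.symptom_effects or {}).items()
        )
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file; omitted keys keep
    their defaults.  ``seed`` overrides the file's seed."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_raw = dict(raw.get("generator", {}))
    effects = gen_raw.pop("symptom_effects", None)
    if effects is None:
        effects_map = dict(DEFAULT_SYMPTOM_EFFECTS)
    else:
        effects_map = {(e["item"], e["subtype"]): float(e["shift"]) for e in effects}
    gen = sdata.GeneratorConfig(symptom_effects=effects_map, **gen_raw)
    cfg = PipelineConfig(
        generator=gen,
        glm=GlmConfig(**raw.get("glm", {})),
        clustering=ClusteringConfig(**raw.get("clustering", {})),
        sda=SdaConfig(**raw.get("sda", {})),
        output_dir=raw.get("output_dir", "pipeline_out"),
        seed=raw.get("seed", 0),
        run_glm=raw.get("run_glm", True),
    )
    if seed is not None:
        cfg.seed = seed
    cfg.generator.seed = cfg.seed
    return cfg


# ---------------------------------------------------------------------------
# Output-table schema validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "cohort.csv": ["subject", "diagnosis", "age", "gender", "latent_subtype"],
    "responses.csv": ["subject", "roi", "phase", "condition", "beta"],
    "contrasts.csv": ["subject", "roi", "phase", "condition", "value"],
    "symptoms.csv": None,  # checked separately
    "events.tsv": ["onset", "duration", "trial_type", "response_time", "outcome"],
    "clusters.csv": ["subject", "subtype"],
    "pca.csv": ["roi", "component", "percent", "se"],
    "scores.csv": ["roi", "subject", "pc1", "pc2"],
    "selection.csv": ["roi", "k", "bic", "p", "significant", "selected"],
    "anova.csv": ["roi", "term", "num_df", "den_df", "F", "p"],
    "rfe_trace.csv": ["step", "n_variables", "removed", "loo_accuracy"],
    "associations.csv": ["item", "class", "r", "p", "bonferroni_significant"],
    "posthoc.csv": ["item", "F", "num_df", "den_df", "p", "p_corrected",
                    "corrected_significant"],
}


def _read(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, comment="#")


def validate_tables(paths: list[str | Path]) -> list[str]:
    """Schema checks for pipeline tables; returns a list of violations
    (empty when everything conforms)."""
    violations = []
    for p in map(Path, paths):
        if not p.exists():
            violations.append(f"{p}: file not found")
            continue
        try:
            df = _read(p)
        except Exception as exc:  # malformed file
            violations.append(f"{p}: unreadable ({exc})")
            continue
        name = p.name
        if name == "symptoms.csv":
            items = [c for c in df.columns if c != "subject"]
            if len(items) != 59:
                violations.append(f"{p}: expected 59 item columns, found {len(items)}")
            for c in items:
                if c not in sdata.ITEM_RANGES:
                    violations.append(f"{p}: unknown item column {c!r}")
                    continue
                lo, hi = sdata.ITEM_RANGES[c]
                vals = df[c].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    violations.append(f"{p}: column {c!r} outside range [{lo},{hi}]")
            if df["subject"].duplicated().any():
                violations.append(f"{p}: duplicate subject ids")
            continue
        cols = _SCHEMAS.get(name)
        if cols is None:
            violations.append(f"{p}: no schema registered for {name}")
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            violations.append(f"{p}: missing columns {missing}")
            continue
        if name == "cohort.csv":
            if df["subject"].duplicated().any():
                violations.append(f"{p}: duplicate subject ids")
            if (df["age"] <= 0).any():
                violations.append(f"{p}: non-positive ages")
        if name == "events.tsv":
            keys = [c for c in ("subject", "session") if c in df.columns]
            grouped = df.groupby(keys)["onset"] if keys else [(None, df["onset"])]
            for _, series in grouped:
                if (series.diff().dropna() < 0).any():
                    violations.append(f"{p}: onsets are not non-decreasing")
                    break
    return violations
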