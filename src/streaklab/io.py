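"""Configuration, serialization and the reproducible pipeline runner.

Interchange formats are deliberately plain: stimulus sets and response
tables are CSV with fixed schemas, manifests are JSON, and configs are YAML
or JSON.  ``run_pipeline`` chains the stages (stimuli → model curves →
cohort simulation → analysis), derives every stage's random stream from the
global seed plus the stage name, and writes a manifest with SHA-256 hashes
of each artifact so identical configs provably yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, synthetic
from .observers import ObserverSpec, PriorSpec, UrnSpec
from .stimuli import DesignConfig, Sequence, StimulusSet, build_stimulus_set, validate_stimulus_set
from .synthetic import RESPONSE_COLUMNS, CohortConfig, study_preset

__all__ = [
    "SchemaError",
    "read_response_table",
    "write_response_table",
    "stimulus_set_from_csv",
    "parse_observer_config",
    "parse_cohort_config",
    "RunConfig",
    "run_pipeline",
    "stage_seed",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable sub-seed for a named pipeline stage (independent streams)."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


# ---------------------------------------------------------------------------
# Response tables


def write_response_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    """Read and validate a trial-level response table.

    Checks the column set, response ranges per format, and uniqueness of
    (participant_id, trial_index); violations are reported with row numbers
    (1-based, excluding the header).
    """
    table = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")

    problems: list[str] = []
    for idx, row in table.iterrows():
        rowno = idx + 1
        fmt = row["format"]
        resp = row["response"]
        if fmt == "continuous":
            if not 0 <= resp <= 100:
                problems.append(f"row {rowno}: rating {resp} outside [0, 100]")
        elif fmt == "dichotomous":
            if resp not in (0, 1):
                problems.append(f"row {rowno}: choice {resp} not in {{0, 1}}")
        else:
            problems.append(f"row {rowno}: unknown format {fmt!r}")
    dup = table.duplicated(subset=["participant_id", "trial_index"], keep=False)
    if dup.any():
        rows = [str(i + 1) for i in table.index[dup][:10]]
        problems.append(f"duplicate (participant_id, trial_index) keys at rows {', '.join(rows)}")
    if problems:
        raise SchemaError("; ".join(problems[:20]))
    return table


# ---------------------------------------------------------------------------
# Stimulus sets


def stimulus_set_from_csv(path) -> StimulusSet:
    """Rehydrate a stimulus session written by ``StimulusSet.to_csv``."""
    frame = pd.read_csv(path)
    needed = {"session_id", "trial_index", "role", "outcomes"}
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"stimulus CSV missing columns: {sorted(missing)}")
    frame = frame.sort_values("trial_index")
    seqs = tuple(Sequence(row.outcomes, role=row.role) for row in frame.itertuples())
    session = str(frame["session_id"].iloc[0])
    seed = int(session.rsplit("-", 1)[-1]) if session.rsplit("-", 1)[-1].isdigit() else -1
    return StimulusSet(seqs, seed=seed)


# ---------------------------------------------------------------------------
# Configs


def _load_config_file(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def parse_observer_config(spec: dict | str | Path) -> ObserverSpec:
    """Build an observer from a config mapping (or YAML/JSON file path).

    Schema::

        family: iid_bayes | urn
        prior: {kind: point|discrete|conjugate, theta|support/probs|alpha,beta}
        N: <urn size>           # urn family only
        renewal: per-sequence   # optional
    """
    if not isinstance(spec, dict):
        spec = _load_config_file(spec)
    try:
        prior_spec = spec["prior"]
        kind = prior_spec["kind"]
        if kind == "point":
            prior = PriorSpec.point(prior_spec["theta"])
        elif kind == "discrete":
            prior = PriorSpec.discrete(prior_spec["support"], prior_spec.get("probs"))
        elif kind == "conjugate":
            prior = PriorSpec.conjugate(prior_spec["alpha"], prior_spec["beta"])
        else:
            raise SchemaError(f"unknown prior kind {kind!r}")
        family = spec["family"]
        if family == "iid_bayes":
            return ObserverSpec.iid(prior)
        if family == "urn":
            urn = UrnSpec(N=spec["N"], prior=prior, renewal=spec.get("renewal", "per-sequence"))
            return ObserverSpec.from_urn(urn)
        raise SchemaError(f"unknown observer family {family!r}")
    except KeyError as exc:
        raise SchemaError(f"observer config missing key {exc}") from exc


def parse_cohort_config(spec: dict | str | Path) -> CohortConfig:
    """Build a cohort config from a mapping/file: either ``{preset: "2A"}``
    (optionally overriding noise_sd/temperature) or a full explicit spec with
    per-condition observers and mixtures."""
    if not isinstance(spec, dict):
        spec = _load_config_file(spec)
    if "preset" in spec:
        cfg = study_preset(spec["preset"])
        overrides = {
            k: spec[k] for k in ("noise_sd", "temperature", "stimulus_seed") if k in spec
        }
        return dataclasses.replace(cfg, **overrides) if overrides else cfg
    try:
        conditions = tuple(
            synthetic.ConditionSpec(
                name=c["name"],
                n=int(c["n"]),
                observer=parse_observer_config(c["observer"]),
                mixture=dict(c["mixture"]),
            )
            for c in spec["conditions"]
        )
        return CohortConfig(
            study_tag=spec["study_tag"],
            response_format=spec["response_format"],
            conditions=conditions,
            noise_sd=float(spec.get("noise_sd", 10.0)),
            temperature=float(spec.get("temperature", 8.0)),
            stimulus_seed=spec.get("stimulus_seed"),
        )
    except KeyError as exc:
        raise SchemaError(f"cohort config missing key {exc}") from exc


# ---------------------------------------------------------------------------
# Pipeline


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration.

    Stage blocks are optional; requesting analysis without a cohort block is
    a configuration error.  Serializes losslessly to/from YAML or JSON.
    """

    seed: int
    out_dir: str
    stimuli: dict = dataclasses.field(default_factory=dict)
    observer: dict | None = None
    cohort: dict | None = None
    analyze: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = _load_config_file(path)
        try:
            return cls(
                seed=int(raw["seed"]),
                out_dir=str(raw["out_dir"]),
                stimuli=raw.get("stimuli", {}),
                observer=raw.get("observer"),
                cohort=raw.get("cohort"),
                analyze=bool(raw.get("analyze", True)),
            )
        except KeyError as exc:
            raise SchemaError(f"run config missing key {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def curve_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "streak_length": [pt.streak_length for pt in curve.points],
            "p_repeat": [pt.p_repeat for pt in curve.points],
            "n_sequences": [pt.n_sequences for pt in curve.points],
            "filler_flag": [pt.filler_flag for pt in curve.points],
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    from .observers import model_curve  # local import to keep module load light

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seeds: dict[str, int] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    # stimuli
    stim_seed = int(config.stimuli.get("seed", stage_seed(config.seed, "stimuli")))
    seeds["stimuli"] = stim_seed
    stimset = build_stimulus_set(stim_seed, DesignConfig(**{
        k: v for k, v in config.stimuli.items() if k != "seed"
    }))
    report = validate_stimulus_set(stimset)
    if not report:
        raise RuntimeError(f"stage stimuli: generated set failed validation: {report.violations}")
    stim_csv = out / "stimuli.csv"
    stimset.to_csv(stim_csv)
    (out / "stimuli.json").write_text(stimset.to_json())
    record("stimuli.csv", stim_csv)
    record("stimuli.json", out / "stimuli.json")

    # model curves
    if config.observer is not None:
        observer = parse_observer_config(config.observer)
        curve = model_curve(observer, stimset)
        path = out / "curves.csv"
        curve_frame(curve).to_csv(path, index=False)
        record("curves.csv", path)

    # cohort simulation
    table = None
    if config.cohort is not None:
        cohort = parse_cohort_config(config.cohort)
        if cohort.stimulus_seed is None:
            cohort = dataclasses.replace(cohort, stimulus_seed=stim_seed)
        sim_seed = stage_seed(config.seed, "cohort")
        seeds["cohort"] = sim_seed
        table = synthetic.simulate_study(cohort, sim_seed)
        path = out / "responses.csv"
        write_response_table(table, path)
        record("responses.csv", path)

    # analysis
    if config.analyze:
        if table is None:
            raise SchemaError("analysis requested but no cohort block configured")
        agg = analysis.aggregate_curve(table)
        agg.to_csv(out / "aggregate_curve.csv", index=False)
        record("aggregate_curve.csv", out / "aggregate_curve.csv")
        fits = analysis.fit_participants(table)
        analysis.fits_frame(fits).to_csv(out / "fits.csv", index=False)
        record("fits.csv", out / "fits.csv")
        shares = analysis.classify_strategies(fits)
        shares.to_csv(out / "strategy_shares.csv")
        record("strategy_shares.csv", out / "strategy_shares.csv")

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "seeds": seeds,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
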