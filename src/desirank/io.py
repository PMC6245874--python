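"""Study tables, run configuration, pipeline orchestration and output files.

Input is one delimited text file per study (TSV or CSV, header row, one
gene-identifier column) holding gene-level results: one row per gene,
columns such as P-value, log2 fold change, odds ratio.  A run configuration
(YAML or JSON) names the studies, assigns each variable a desirability
function, and sets integration / permutation / hard-threshold options.

Gene identifiers are matched exactly after whitespace stripping and case
folding; any richer cross-annotation mapping belongs upstream.  Duplicate
gene rows within a study keep, per variable, the value most favourable
under that variable's desirability orientation (conservative toward
candidate retention) and are reported in the log.

Outputs: ``results.tsv`` (per-gene d_overall, rank, desirable flag),
``d_study.tsv``, ``percentile_ranks.tsv``, optional ``null_summary.json``,
``significance.tsv`` and ``intersections.tsv``, plus ``run_log.txt``.
Floats are serialised at 12 significant digits for reproducible diffs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .integration import (
    ConfigError,
    DesirabilityMatrix,
    integrate_studies,
    integrate_variables,
    percentile_ranks,
)
from .nulls import hard_threshold, intersection_counts, permutation_null
from .transforms import (
    DegenerateVariableError,
    DesirabilityFunctionSpec,
    transform_variable,
)

__all__ = [
    "FormatError",
    "StudyTable",
    "StudyConfig",
    "RunConfig",
    "PRESETS",
    "preset_spec",
    "normalize_gene_id",
    "read_study",
    "harmonize_genes",
    "study_desirabilities",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("desirank")

FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """An input study file does not have the expected tabular layout."""


# --------------------------------------------------------------------------
# presets: the three shipped cut-point configurations
#
# iR-none  no customisation: each variable is rescaled linearly over its
#          observed range (percentile cuts 0-100; fold-change valley over
#          min / median / max).
# iR-num   fixed numeric cuts: P in (0.0001, 0.1); fold change saturating
#          beyond +-1.5 and zero within +-0.5 (log2 equivalents available).
# iR-per   percentile cuts: P in (5%, 95%); fold-change tails beyond the
#          5th/95th percentile desirable, middle 50% zero.
# --------------------------------------------------------------------------

_LOG2_3 = math.log2(3.0)
_LOG2_15 = math.log2(1.5)

PRESETS: dict[str, dict[str, dict]] = {
    "iR-none": {
        "p_value": {"kind": "low", "cuts": (0, 100), "cut_mode": "percentile"},
        "fold_change": {
            "kind": "extreme",
            "cuts": (0, 50, 50, 100),
            "cut_mode": "percentile",
        },
        "odds_ratio": {"kind": "high", "cuts": (0, 100), "cut_mode": "percentile"},
    },
    "iR-num": {
        "p_value": {"kind": "low", "cuts": (0.0001, 0.1)},
        "fold_change": {"kind": "extreme", "cuts": (-1.5, -0.5, 0.5, 1.5)},
        "log2_fold_change": {
            "kind": "extreme",
            "cuts": (-_LOG2_3, -_LOG2_15, _LOG2_15, _LOG2_3),
        },
        "odds_ratio": {"kind": "high", "cuts": (1.0, 3.0)},
    },
    "iR-per": {
        "p_value": {"kind": "low", "cuts": (5, 95), "cut_mode": "percentile"},
        "fold_change": {
            "kind": "extreme",
            "cuts": (5, 50, 95),
            "cut_mode": "percentile",
        },
        "odds_ratio": {"kind": "high", "cuts": (5, 95), "cut_mode": "percentile"},
    },
}
# log2 fold changes behave like raw ones under percentile presets
for _p in ("iR-none", "iR-per"):
    PRESETS[_p]["log2_fold_change"] = PRESETS[_p]["fold_change"]


def preset_spec(preset: str, role: str, weight: float = 1.0) -> DesirabilityFunctionSpec:
    """Desirability spec for a variable role under a named preset."""
    try:
        params = PRESETS[preset][role]
    except KeyError:
        raise ConfigError(
            f"no preset rule for role {role!r} under preset {preset!r}"
        ) from None
    return DesirabilityFunctionSpec(weight=weight, **params)


# --------------------------------------------------------------------------
# study tables
# --------------------------------------------------------------------------


@dataclass
class StudyTable:
    """One study's gene-by-variable values plus metadata.

    ``data`` is indexed by normalised gene_id with one float column per
    configured variable (NaN = missing).  ``variable_specs`` maps variable
    name to its desirability spec; ``p_adjusted`` / ``p_unadjusted`` name
    the P-value columns used by the hard-threshold baseline.
    """

    study_id: str
    data: pd.DataFrame
    variable_specs: dict[str, DesirabilityFunctionSpec]
    weight: float = 1.0
    p_adjusted: str | None = None
    p_unadjusted: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"study {self.study_id!r}: negative weight")
        missing = [v for v in self.variable_specs if v not in self.data.columns]
        if missing:
            raise ConfigError(
                f"study {self.study_id!r}: configured variables {missing} "
                "not present as columns"
            )
        if not self.data.index.is_unique:
            raise ValueError(f"study {self.study_id!r}: duplicate gene ids")

    @property
    def genes(self) -> pd.Index:
        return self.data.index


@dataclass
class StudyConfig:
    """Per-study block of the run configuration."""

    study_id: str
    path: str
    gene_column: str = "gene_id"
    weight: float = 1.0
    variables: dict[str, DesirabilityFunctionSpec] = field(default_factory=dict)
    p_adjusted: str | None = None
    p_unadjusted: str | None = None


@dataclass
class RunConfig:
    """Full run configuration: studies plus integration/null/baseline options."""

    studies: list[StudyConfig]
    mode: str = "normalized"
    permutations: int = 0
    seed: int = 0
    hard_thresh: bool = False
    adj_p_cut: float = 0.1
    raw_p_cut: float = 0.05

    def __post_init__(self) -> None:
        if not self.studies:
            raise ConfigError("configuration names no studies")


def normalize_gene_id(g) -> str:
    """Canonical gene identifier: stripped, case-folded (upper)."""
    return str(g).strip().upper()


def _spec_from_dict(d: dict) -> DesirabilityFunctionSpec:
    known = {f.name for f in dataclasses.fields(DesirabilityFunctionSpec)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown desirability spec fields: {sorted(unknown)}")
    return DesirabilityFunctionSpec(**d)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration file.

    Each study block: ``id``, ``path``, ``gene_column``, optional ``weight``,
    ``p_adjusted``/``p_unadjusted``, and ``variables`` mapping column name to
    either a spec dict (kind, cuts, ...) or ``{"preset": NAME, "role": ROLE}``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "studies" not in raw:
        raise ConfigError(f"{path}: configuration must be a mapping with 'studies'")
    preset_default = raw.get("preset")
    studies = []
    for block in raw["studies"]:
        variables = {}
        for var, vs in (block.get("variables") or {}).items():
            if isinstance(vs, str):  # role name -> resolve via preset
                if preset_default is None:
                    raise ConfigError(
                        f"variable {var!r} uses role shorthand but no preset is set"
                    )
                variables[var] = preset_spec(preset_default, vs)
            elif "role" in vs:
                variables[var] = preset_spec(
                    vs.get("preset", preset_default), vs["role"],
                    weight=vs.get("weight", 1.0),
                )
            else:
                variables[var] = _spec_from_dict(vs)
        spath = Path(block["path"])
        if not spath.is_absolute():
            spath = path.parent / spath
        studies.append(
            StudyConfig(
                study_id=str(block["id"]),
                path=str(spath),
                gene_column=block.get("gene_column", "gene_id"),
                weight=float(block.get("weight", 1.0)),
                variables=variables,
                p_adjusted=block.get("p_adjusted"),
                p_unadjusted=block.get("p_unadjusted"),
            )
        )
    return RunConfig(
        studies=studies,
        mode=raw.get("mode", "normalized"),
        permutations=int(raw.get("permutations", 0)),
        seed=int(raw.get("seed", 0)),
        hard_thresh=bool(raw.get("hard_thresh", False)),
        adj_p_cut=float(raw.get("adj_p_cut", 0.1)),
        raw_p_cut=float(raw.get("raw_p_cut", 0.05)),
    )


# --------------------------------------------------------------------------
# reading and harmonising studies
# --------------------------------------------------------------------------


def _dedupe(df: pd.DataFrame, specs: dict[str, DesirabilityFunctionSpec],
            study_id: str) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the most desirable value per
    variable under its spec's orientation (low -> min, high -> max,
    extreme -> farthest from the valley centre, target -> closest to C)."""
    n_dup = df.index.duplicated().sum()
    if n_dup == 0:
        return df
    logger.warning(
        "study %s: %d duplicate gene rows collapsed to the most desirable "
        "value per variable", study_id, n_dup,
    )
    groups = df.groupby(level=0, sort=False)

    def pick(col: pd.Series, spec: DesirabilityFunctionSpec | None):
        def agg(s: pd.Series):
            s = s.dropna()
            if s.empty:
                return np.nan
            if spec is None or spec.kind == "low":
                return s.min()
            if spec.kind == "high":
                return s.max()
            if spec.kind == "extreme":
                centre = (
                    (spec.cuts[1] + spec.cuts[2]) / 2.0
                    if spec.is_numeric and len(spec.cuts) == 4
                    else float(col.median())
                )
                return s.loc[(s - centre).abs().idxmax()]
            # target: closest to the peak C
            centre = spec.cuts[1] if spec.is_numeric else float(col.median())
            return s.loc[(s - centre).abs().idxmin()]
        return agg

    out = pd.DataFrame(
        {c: groups[c].agg(pick(df[c], specs.get(c))) for c in df.columns}
    )
    return out.loc[df.index.drop_duplicates()]


def read_study(path, cfg: StudyConfig) -> StudyTable:
    """Load one study's gene-level table.

    The file must be delimited text (TSV/CSV inferred from the extension,
    tab assumed otherwise) with a header containing ``cfg.gene_column``.
    Configured variable columns are parsed as floats; unparseable cells
    become missing and are counted in the log.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if cfg.gene_column not in df.columns:
        raise FormatError(
            f"{path}: gene column {cfg.gene_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    for var in cfg.variables:
        if var not in df.columns:
            raise ConfigError(
                f"study {cfg.study_id!r}: variable {var!r} not found in {path}"
            )
    df = df.set_index(df[cfg.gene_column].map(normalize_gene_id))
    df.index.name = "gene_id"
    keep = list(cfg.variables) or [c for c in df.columns if c != cfg.gene_column]
    parsed = {}
    for col in keep:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() & (df[col].str.strip() != "") \
            & (df[col].str.upper() != "NA")
        if bad.any():
            logger.warning(
                "study %s: %d unparseable values in %r treated as missing",
                cfg.study_id, int(bad.sum()), col,
            )
        parsed[col] = numeric.astype(float)
    out = pd.DataFrame(parsed, index=df.index)
    out = _dedupe(out, cfg.variables, cfg.study_id)
    logger.info("study %s: %d genes, %d variables", cfg.study_id,
                out.shape[0], out.shape[1])
    return StudyTable(
        study_id=cfg.study_id,
        data=out,
        variable_specs=dict(cfg.variables),
        weight=cfg.weight,
        p_adjusted=cfg.p_adjusted,
        p_unadjusted=cfg.p_unadjusted,
    )


def harmonize_genes(studies) -> pd.Index:
    """Union gene universe across studies (exact match after normalisation)."""
    studies = list(studies)
    if not studies:
        raise ConfigError("no studies to harmonise")
    universe: set[str] = set()
    for st in studies:
        universe.update(st.genes)
    idx = pd.Index(sorted(universe), name="gene_id")
    logger.info("gene universe: %d genes across %d studies", len(idx), len(studies))
    return idx


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def study_desirabilities(study: StudyTable) -> pd.Series:
    """Transform a study's variables and combine them into d_study.

    Variables that cannot resolve percentile cuts (fewer than two distinct
    values) are skipped with a warning; a study whose every variable is
    degenerate yields an empty series.
    """
    cols = {}
    weights = {}
    for var, spec in study.variable_specs.items():
        try:
            cols[var] = transform_variable(study.data[var], spec)
        except DegenerateVariableError as exc:
            logger.warning("study %s: variable %r skipped (%s)",
                           study.study_id, var, exc)
            continue
        weights[var] = spec.weight
    if not cols:
        return pd.Series(dtype=float, name="d_study")
    d_vars = pd.DataFrame(cols, index=study.data.index)
    return integrate_variables(d_vars, pd.Series(weights))


def build_matrix(studies) -> DesirabilityMatrix:
    """Per-study d_study for every study, aligned on the union gene universe."""
    studies = list(studies)
    universe = harmonize_genes(studies)
    cols = {}
    weights = {}
    for st in studies:
        cols[st.study_id] = study_desirabilities(st).reindex(universe)
        weights[st.study_id] = st.weight
    d_study = pd.DataFrame(cols, index=universe)
    observed = d_study.notna().any(axis=1)
    if not observed.all():
        d_study = d_study[observed]
    return DesirabilityMatrix(d_study, pd.Series(weights))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir) -> pd.DataFrame:
    """Execute the full integration run and write result files.

    Steps: read studies -> transform variables -> d_study -> d_overall
    (with ranks and the desirable flag) -> optional permutation null and
    hard-threshold baseline.  Deterministic given the config seed.
    Returns the per-gene results frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        studies = [read_study(sc.path, sc) for sc in config.studies]
        matrix = build_matrix(studies)
        result = integrate_studies(matrix, mode=config.mode)

        _write_tsv(matrix.d_study.join(result[["n_present"]]).sort_index(),
                   out_dir / "d_study.tsv")
        _write_tsv(percentile_ranks(matrix.d_study).sort_index(),
                   out_dir / "percentile_ranks.tsv")
        _write_tsv(
            result[
                ["d_overall_raw", "d_overall", "n_present", "n_missing",
                 "rank", "desirable"]
            ],
            out_dir / "results.tsv",
        )

        if config.permutations > 0:
            null = permutation_null(
                matrix, n_permutations=config.permutations,
                seed=config.seed, mode=config.mode,
            )
            summary = null.summary()
            summary["observed_mean"] = float(result["d_overall"].mean())
            with open(out_dir / "null_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            logger.info("permutation null mean %.6g (observed %.6g)",
                        null.mean, summary["observed_mean"])

        if config.hard_thresh:
            sig = hard_threshold(
                studies, adj_p_cut=config.adj_p_cut, raw_p_cut=config.raw_p_cut
            )
            _write_tsv(sig, out_dir / "significance.tsv")
            intersection_counts(sig).to_csv(
                out_dir / "intersections.tsv", sep="\t", index=False
            )
        logger.info("wrote results for %d genes to %s", result.shape[0], out_dir)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
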