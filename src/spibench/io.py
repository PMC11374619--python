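"""CSV/YAML readers and writers.

Interchange dialect: comma-delimited UTF-8 with "." decimal mark.  A
decision matrix file has a mandatory header row of indicator ids and a
first column of alternative ids.  The indicator specification is a CSV with
columns ``id,name,category,direction``.  Pipeline configs are flat YAML
mappings whose keys match :class:`~spibench.types.PipelineConfig` fields.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import DecisionMatrix, EvaluationResult, IndicatorSpec, PipelineConfig

PathLike = Union[str, Path]


def read_indicator_specs(path: PathLike) -> list[IndicatorSpec]:
    df = pd.read_csv(path, dtype=str).fillna("")
    if "id" not in df.columns or "direction" not in df.columns:
        raise ValueError("indicator spec file needs 'id' and 'direction' columns")
    return [IndicatorSpec(id=row["id"],
                          name=row.get("name", ""),
                          category=row.get("category", "system") or "system",
                          direction=row["direction"])
            for _, row in df.iterrows()]


def write_indicator_specs(specs: Sequence[IndicatorSpec],
                          path: PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in specs]).to_csv(path,
                                                                index=False)


def read_decision_matrix(path: PathLike,
                         spec: Union[PathLike, Sequence[IndicatorSpec]],
                         label: str = "") -> DecisionMatrix:
    """Parse a decision-matrix CSV against an indicator specification.

    Errors name the offending cell (missing or non-numeric values), any
    header id absent from the spec, and duplicate alternative ids.
    """
    if isinstance(spec, (str, Path)):
        spec = read_indicator_specs(spec)
    by_id = {s.id: s for s in spec}

    df = pd.read_csv(path, index_col=0)
    header_ids = [str(c) for c in df.columns]
    unknown = [c for c in header_ids if c not in by_id]
    if unknown:
        raise ValueError(f"indicator id(s) not in spec: {unknown}")
    alternatives = [str(a) for a in df.index]
    dupes = sorted({a for a in alternatives if alternatives.count(a) > 1})
    if dupes:
        raise ValueError(f"duplicate alternative id(s): {dupes}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing or non-numeric value at row {alternatives[i]!r}, "
            f"column {header_ids[j]!r}")

    indicators = [by_id[c] for c in header_ids]
    return DecisionMatrix(alternatives=alternatives, indicators=indicators,
                          values=numeric.to_numpy(dtype=float),
                          label=label or str(path))


def write_decision_matrix(R: DecisionMatrix, path: PathLike) -> None:
    """Write a matrix CSV that round-trips values exactly."""
    R.to_frame().to_csv(path, float_format="%.17g",
                        index_label="alternative")


def load_config(path: PathLike) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key-value mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def write_results(result: EvaluationResult, out_dir: PathLike,
                  indicators: Sequence[IndicatorSpec] | None = None) -> None:
    """Write the per-alternative result CSV, the weight CSV and a report.

    ``scores.csv``: alternative, score, rank, group, is_benchmark.
    ``weights.csv``: indicator, weight (ordered as in the input matrix).
    ``report.txt``: stage choices, weights, grid-search outcome.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "scores.csv", index=False)

    ids = ([s.id for s in indicators] if indicators is not None
           else [f"c{j + 1}" for j in range(result.weights.weights.size)])
    pd.DataFrame({"indicator": ids,
                  "weight": result.weights.weights}).to_csv(
        out / "weights.csv", index=False)

    rep = result.clusters.report
    lines = [
        f"normalization: {result.config.normalization}",
        f"weighting: {result.config.weighting}",
        f"aggregation: {result.config.aggregation}",
        f"clustering source: {result.clusters.source}",
        f"grid combos evaluated: {rep.n_total_combos}",
        f"grid combos valid: {rep.n_valid_combos}",
        f"grid best eps: {rep.eps_best}",
        f"grid best minPts: {rep.minpts_best}",
        f"grid best mean silhouette: {rep.silhouette_best}",
        "benchmarks: " + ", ".join(
            f"group {g} -> {a}" for g, a in sorted(
                result.clusters.benchmarks.items())),
    ]
    (out / "report.txt").write_text("\n".join(lines) + "\n",
                                    encoding="utf-8")
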