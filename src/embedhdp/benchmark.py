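"""Human-correlation benchmark harness.

Loads suggestion / ground-truth pair datasets with per-rater human scores,
applies the length filter, scores every kept pair with a panel of metrics,
and reports the correlation of each metric with the aggregated human score
— the design under which the topic metric is compared against BLEU, ROUGE
and cosine baselines.  A metric failing on a single pair loses that pair
(logged, excluded from its n_used), not the whole panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines
from .embeddings import EmbeddingBackend
from .errors import (
    EmbedHdpError,
    InvalidInputError,
    MalformedRowError,
    SchemaError,
    UndefinedCorrelationError,
)
from .metric import MetricConfig, PairRecord, embedhdp_score, length_filter
from .textproc import tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dataset:
    records: tuple[PairRecord, ...]
    source: str = ""

    @property
    def n(self) -> int:
        return len(self.records)


def load_dataset(path: str | Path, require_human: bool = True) -> Dataset:
    """Read a pair dataset from CSV (or TSV by extension).

    Required columns: ``suggestion`` and ``ground_truth``; human scores in
    a single ``human`` column or ``human_1..human_k``; an optional ``id``
    column.  Malformed rows (empty sentence, non-finite score) are rejected
    together, with their 1-based file line numbers in the error message.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty dataset file") from exc
    if df.empty:
        raise SchemaError(f"{path}: dataset has a header but no rows")

    for col in ("suggestion", "ground_truth"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    human_cols = [c for c in df.columns if c == "human" or c.startswith("human_")]
    if require_human and not human_cols:
        raise SchemaError(f"{path}: no 'human' or 'human_1..k' column found")

    records: list[PairRecord] = []
    bad_lines: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        rowd = dict(zip(df.columns, row))
        suggestion = rowd["suggestion"].strip()
        ground_truth = rowd["ground_truth"].strip()
        pair_id = rowd.get("id", "").strip() or f"row{line_no}"
        if not suggestion or not ground_truth:
            bad_lines.append(f"line {line_no}: empty sentence")
            continue
        scores: tuple[float, ...] | None = None
        if human_cols:
            try:
                scores = tuple(float(rowd[c]) for c in human_cols if rowd[c].strip())
            except ValueError:
                bad_lines.append(f"line {line_no}: non-numeric human score")
                continue
            if not scores or not all(np.isfinite(scores)):
                bad_lines.append(f"line {line_no}: missing or non-finite human score")
                continue
        records.append(PairRecord(suggestion, ground_truth, scores, pair_id))

    if bad_lines:
        raise MalformedRowError(f"{path}: " + "; ".join(bad_lines))
    return Dataset(tuple(records), source=str(path))


def aggregate_human(scores: Sequence[float], method: str = "mean") -> float:
    """Collapse multi-rater scores to one number (mean by default)."""
    if not scores:
        raise InvalidInputError("cannot aggregate an empty score list")
    arr = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("non-finite human score")
    if method == "mean":
        return float(arr.mean())
    if method == "median":
        return float(np.median(arr))
    raise InvalidInputError(f"unknown aggregation method: {method!r}")


def _check_corr_inputs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise InvalidInputError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if len(xa) < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    return xa, ya


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient, in [-1, 1]."""
    xa, ya = _check_corr_inputs(x, y)
    return float(np.clip(stats.pearsonr(xa, ya).statistic, -1.0, 1.0))


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation, available behind the harness flag."""
    xa, ya = _check_corr_inputs(x, y)
    return float(np.clip(stats.spearmanr(xa, ya).statistic, -1.0, 1.0))


PairScorer = Callable[[PairRecord], float]


def _panel(cfg: MetricConfig, backend: EmbeddingBackend) -> dict[str, PairScorer]:
    """Built-in metric panel keyed by CLI-facing names."""

    def toks(text: str):
        return tokenize(text, mode=cfg.tokenizer_mode,
                        attach_particles=cfg.attach_particles, particles=cfg.particles)

    return {
        "embedhdp": lambda p: embedhdp_score(p, cfg, backend).value,
        "bleu": lambda p: baselines.bleu(toks(p.suggestion), toks(p.ground_truth)),
        "rouge1": lambda p: baselines.rouge_n(toks(p.suggestion), toks(p.ground_truth), 1).f,
        "rouge2": lambda p: baselines.rouge_n(toks(p.suggestion), toks(p.ground_truth), 2).f,
        "rougeL": lambda p: baselines.rouge_l(toks(p.suggestion), toks(p.ground_truth)).f,
        "cosine": lambda p: baselines.bow_cosine(toks(p.suggestion), toks(p.ground_truth)),
    }


@dataclass(frozen=True)
class MetricResult:
    r: float | None
    n_used: int
    error: str | None = None


@dataclass(frozen=True)
class BenchmarkReport:
    per_metric: dict[str, MetricResult]
    n_input: int
    n_kept: int
    n_removed: int
    correlation: str
    config_digest: str

    def to_json(self) -> str:
        """Canonical serialization: sorted keys, repr floats — byte-stable
        across runs of the same seeded configuration."""
        payload = {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "correlation": self.correlation,
            "config_digest": self.config_digest,
            "metrics": {
                name: {"r": res.r, "n_used": res.n_used, "error": res.error}
                for name, res in self.per_metric.items()
            },
        }
        return json.dumps(payload, sort_keys=True, ensure_ascii=False)

    def to_markdown(self) -> str:
        lines = ["| Evaluation metric | Correlation coefficient | n |",
                 "|---|---|---|"]
        ranked = sorted(
            self.per_metric.items(),
            key=lambda kv: -kv[1].r if kv[1].r is not None else 1.0,
        )
        for name, res in ranked:
            r_txt = f"{res.r:.2f}" if res.r is not None else f"undefined ({res.error})"
            lines.append(f"| {name} | {r_txt} | {res.n_used} |")
        return "\n".join(lines)


def run_benchmark(
    ds: Dataset,
    metrics: Sequence[str] | Mapping[str, PairScorer],
    cfg: MetricConfig,
    backend: EmbeddingBackend,
    correlation: str = "pearson",
    aggregate: str = "mean",
) -> BenchmarkReport:
    """Score a metric panel on a dataset and correlate with human judgments.

    The length filter runs first; each metric is then scored on the kept
    pairs, and its correlation with the aggregated human scores is
    computed over the pairs it scored successfully.  ``metrics`` is either
    a list of built-in panel names or a mapping of name -> scorer callable.
    """
    if ds.n == 0:
        raise InvalidInputError("empty dataset")
    kept, removed = length_filter(ds.records, cfg)
    if not kept:
        raise InvalidInputError("all pairs were removed by the length filter")

    if isinstance(metrics, Mapping):
        scorers = dict(metrics)
    else:
        panel = _panel(cfg, backend)
        unknown = [m for m in metrics if m not in panel]
        if unknown:
            raise InvalidInputError(f"unknown metric name(s): {unknown}")
        scorers = {m: panel[m] for m in metrics}
    corr_fn = {"pearson": pearson_r, "spearman": spearman_r}.get(correlation)
    if corr_fn is None:
        raise InvalidInputError(f"unknown correlation: {correlation!r}")

    human = {
        p.id: aggregate_human(p.human_scores, aggregate)
        for p in kept
        if p.human_scores
    }
    missing = [p.id for p in kept if p.id not in human]
    if missing:
        raise InvalidInputError(f"pairs without human scores: {missing[:5]}")

    per_metric: dict[str, MetricResult] = {}
    for name, scorer in scorers.items():
        xs: list[float] = []
        ys: list[float] = []
        for pair in kept:
            try:
                value = float(scorer(pair))
            except EmbedHdpError as exc:
                logger.warning("metric %s failed on pair %s: %s", name, pair.id, exc)
                continue
            xs.append(value)
            ys.append(human[pair.id])
        try:
            r = corr_fn(xs, ys)
            per_metric[name] = MetricResult(r=r, n_used=len(xs))
        except UndefinedCorrelationError as exc:
            per_metric[name] = MetricResult(r=None, n_used=len(xs), error=str(exc))

    return BenchmarkReport(
        per_metric=per_metric,
        n_input=ds.n,
        n_kept=len(kept),
        n_removed=len(removed),
        correlation=correlation,
        config_digest=cfg.digest(backend.name),
    )
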