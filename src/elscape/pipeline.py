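"""Per-subject pipeline (fit → landscape → walk → Gini) and the batch driver.

``subject_indices`` turns one binary state series into the pair of
polarization indices that is the analysis's classification surface: the Gini
coefficient of the per-attractor dwelling times and the Gini coefficient of
the pairwise transition counts of a Metropolis walk on the fitted landscape.
``run_pipeline`` maps a manifest of recordings (brain-route, LLM-route with
per-layer analysis and cross-layer averaging, or already-binary series)
through that per-subject pipeline and performs the group comparisons and
behavior correlations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as elio
from .dynamics import DEFAULT_BURN_IN, DEFAULT_N_STEPS, random_walk, summarize_dynamics
from .landscape import assign_basins, build_disconnectivity, find_local_minima
from .mem import (
    empirical_moments,
    exact_distribution,
    fit_accuracy,
    fit_independent,
    fit_pairwise,
)
from .preprocess import (
    BinaryStateSeries,
    LLMSeriesMeta,
    binarize_brain_route,
    per_layer_series,
)
from .stats import compare_groups, correlate_with_behavior, gini, gini_defined

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the per-subject analysis; defaults are the study conditions."""

    learning_rate: float = 0.2
    tol: float = 1e-5
    max_iter: int = 100_000
    n_steps: int = DEFAULT_N_STEPS
    burn_in: int = DEFAULT_BURN_IN
    dwell_statistic: str = "run_length"  # or "occupancy"
    include_zero_pairs: bool = True
    threshold_mode: str = "per_timepoint_global_mean"
    kmeans_restarts: int = 10
    window_start: int = 10_000
    window_end: int = 60_000
    welch: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PolarizationIndices:
    """Per-subject (or per-layer) pair of Gini polarization indices."""

    gini_dwell: float
    gini_trans: float
    source: str = ""
    layer: int | None = None
    dwell_defined: bool = True
    trans_defined: bool = True
    r_d: float | None = None
    n_minima: int | None = None


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def dwell_vector(summary, config: PipelineConfig) -> np.ndarray:
    """Per-attractor dwelling statistic fed to the Gini index."""
    labels = sorted(summary.occupancy)
    if config.dwell_statistic == "run_length":
        return np.array([summary.dwell_mean[l] for l in labels], dtype=float)
    if config.dwell_statistic == "occupancy":
        return np.array([summary.occupancy[l] for l in labels], dtype=float)
    raise ValueError(f"unknown dwell_statistic {config.dwell_statistic!r}")


def transition_vector(summary, config: PipelineConfig) -> np.ndarray:
    """Switch counts per unordered attractor pair.

    With ``include_zero_pairs`` every pair of attractors observed in the
    trajectory contributes an entry, even when the pair never exchanged.
    """
    observed = sorted(summary.occupancy)
    if config.include_zero_pairs:
        pairs = list(itertools.combinations(observed, 2))
    else:
        pairs = sorted(summary.transitions)
    return np.array([summary.transitions.get(p, 0) for p in pairs], dtype=float)


def subject_indices(
    series: BinaryStateSeries | np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PolarizationIndices:
    """Full per-subject analysis of one binary state series.

    Fits the independent and pairwise maximum-entropy models, builds the
    energy landscape and basins, runs the Metropolis walk, and returns the
    Gini coefficients of the dwelling-time and transition-frequency vectors
    (with r_D and the number of local minima attached as metadata).
    """
    config = config or PipelineConfig()
    values = np.asarray(series)
    source = series.source if isinstance(series, BinaryStateSeries) else "array"
    layer = series.layer if isinstance(series, BinaryStateSeries) else None

    def run(stage: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(stage, exc) from exc

    moments = run("moments", empirical_moments, values)
    pairwise = run(
        "fit_pairwise",
        fit_pairwise,
        moments,
        learning_rate=config.learning_rate,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    independent = run("fit_independent", fit_independent, moments)
    accuracy = run("fit_accuracy", fit_accuracy, values, pairwise, independent)
    table = run("exact_distribution", exact_distribution, pairwise)
    minima = run("find_local_minima", find_local_minima, table)
    basins = run("assign_basins", assign_basins, table, minima)
    traj = run(
        "random_walk",
        random_walk,
        table,
        basins,
        n_steps=config.n_steps,
        burn_in=config.burn_in,
        seed=seed,
    )
    summary = run("summarize_dynamics", summarize_dynamics, traj)

    dv = dwell_vector(summary, config)
    tv = transition_vector(summary, config)
    dwell_ok = gini_defined(dv)
    trans_ok = gini_defined(tv)
    return PolarizationIndices(
        gini_dwell=gini(dv) if dwell_ok else 0.0,
        gini_trans=gini(tv) if trans_ok else 0.0,
        source=source,
        layer=layer,
        dwell_defined=dwell_ok,
        trans_defined=trans_ok,
        r_d=accuracy.r_d if accuracy.defined else None,
        n_minima=len(minima),
    )


def layer_average(per_layer: list[PolarizationIndices]) -> PolarizationIndices:
    """Arithmetic mean of the two indices over layers with defined values."""
    defined = [p for p in per_layer if p.dwell_defined and p.trans_defined]
    skipped = len(per_layer) - len(defined)
    if skipped:
        logger.warning("layer_average: skipping %d layer(s) with undefined indices", skipped)
    if not defined:
        raise ValueError("all layers have undefined polarization indices")
    r_ds = [p.r_d for p in defined if p.r_d is not None]
    return PolarizationIndices(
        gini_dwell=float(np.mean([p.gini_dwell for p in defined])),
        gini_trans=float(np.mean([p.gini_trans for p in defined])),
        source=defined[0].source,
        layer=None,
        r_d=float(np.mean(r_ds)) if r_ds else None,
        n_minima=None,
    )


@dataclass
class PipelineResult:
    results: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_input(row: pd.Series, config: PipelineConfig) -> BinaryStateSeries | list[BinaryStateSeries]:
    route = row["route"]
    path = Path(row["path"])
    if route == "binary":
        return elio.read_binary_series_tsv(path)
    if route == "brain":
        df = elio.read_series_tsv(path)
        return binarize_brain_route(df.to_numpy(dtype=float), config.threshold_mode)
    if route == "llm":
        # a directory of layer_<i>.tsv hidden-state matrices
        layer_files = sorted(path.glob("layer_*.tsv"), key=lambda p: int(p.stem.split("_")[1]))
        if len(layer_files) < 2:
            raise ValueError(f"llm route expects >= 2 layer_<i>.tsv files in {path}")
        stacked = {
            int(p.stem.split("_")[1]): elio.read_series_tsv(p).to_numpy(dtype=float)
            for p in layer_files
        }
        first = next(iter(stacked.values()))
        meta = LLMSeriesMeta(
            n_hidden=first.shape[1],
            n_layers=len(stacked),
            n_iterations=first.shape[0],
            window_start=config.window_start,
            window_end=config.window_end,
        )
        return per_layer_series(stacked, meta, restarts=config.kmeans_restarts)
    raise ValueError(f"unknown route {route!r}")


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Batch driver: per-input polarization indices, group stats, correlations.

    The manifest (DataFrame or TSV path) needs columns ``id``, ``path``,
    ``route`` (brain | llm | binary) and ``group``; an optional ``score``
    column feeds the behavior correlations.  Failed inputs are recorded and
    skipped.  Outputs (results, comparisons, correlations, config) are
    written to ``out_dir`` as TSV/JSON with stable formatting, so a rerun
    with the same manifest and seed is byte-identical.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    required = {"id", "path", "route", "group"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(missing)}")

    rows: list[dict] = []
    failures: list[dict] = []
    for i, row in manifest.reset_index(drop=True).iterrows():
        walk_seed = seed + int(i)
        try:
            loaded = _load_input(row, config)
            if isinstance(loaded, list):
                per_layer = [
                    subject_indices(s, config, seed=walk_seed * 1000 + (s.layer or 0))
                    for s in loaded
                ]
                idx = layer_average(per_layer)
            else:
                idx = subject_indices(loaded, config, seed=walk_seed)
        except Exception as exc:  # noqa: BLE001 - batch driver records and continues
            logger.error("input %s failed: %s", row["id"], exc)
            failures.append({"id": row["id"], "error": str(exc)})
            continue
        rows.append(
            {
                "id": row["id"],
                "group": row["group"],
                "route": row["route"],
                "gini_dwell": idx.gini_dwell,
                "gini_trans": idx.gini_trans,
                "dwell_defined": idx.dwell_defined,
                "trans_defined": idx.trans_defined,
                "r_d": idx.r_d,
                "n_minima": idx.n_minima,
                "score": row.get("score", np.nan),
            }
        )
    results = pd.DataFrame(rows)

    comparisons = _group_comparisons(results, config)
    correlations = _behavior_correlations(results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False, float_format=elio.FLOAT_FORMAT)
        comparisons.to_csv(
            out / "group_comparisons.tsv", sep="\t", index=False, float_format=elio.FLOAT_FORMAT
        )
        correlations.to_csv(
            out / "correlations.tsv", sep="\t", index=False, float_format=elio.FLOAT_FORMAT
        )
        elio.write_json(out / "config.json", {"config": config.to_dict(), "seed": seed})

    return PipelineResult(
        results=results, comparisons=comparisons, correlations=correlations, failures=failures
    )


def _group_comparisons(results: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    if results.empty:
        return pd.DataFrame(
            columns=["index", "group_a", "group_b", "t", "df", "p_raw", "p_bonferroni", "eta_sq"]
        )
    groups = sorted(results["group"].unique())
    pairs = list(itertools.combinations(groups, 2))
    tests = [(idx, a, b) for idx in ("gini_dwell", "gini_trans") for a, b in pairs]
    eligible = [
        (idx, a, b)
        for idx, a, b in tests
        if (results["group"] == a).sum() >= 2 and (results["group"] == b).sum() >= 2
    ]
    n_comp = len(eligible)
    for idx_name, a, b in eligible:
        va = results.loc[results["group"] == a, idx_name].to_numpy()
        vb = results.loc[results["group"] == b, idx_name].to_numpy()
        cmp = compare_groups(va, vb, n_comparisons=n_comp, welch=config.welch)
        rows.append(
            {
                "index": idx_name,
                "group_a": a,
                "group_b": b,
                "t": cmp.t,
                "df": cmp.df,
                "p_raw": cmp.p_raw,
                "p_bonferroni": cmp.p_bonferroni,
                "eta_sq": cmp.eta_sq,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
            }
        )
    return pd.DataFrame(rows)


def _behavior_correlations(results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if results.empty or "score" not in results or results["score"].isna().all():
        return pd.DataFrame(columns=["index", "group", "r", "n", "p"])
    for group, sub in results.groupby("group"):
        scored = sub.dropna(subset=["score"])
        if len(scored) < 3:
            continue
        for idx_name in ("gini_dwell", "gini_trans"):
            corr = correlate_with_behavior(
                scored[idx_name].to_numpy(), scored["score"].to_numpy()
            )
            rows.append(
                {
                    "index": idx_name,
                    "group": group,
                    "r": corr.r,
                    "n": corr.n,
                    "p": corr.p,
                    "defined": corr.defined,
                }
            )
    return pd.DataFrame(rows)
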