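"""Temporal monitoring of a campaign: metric tracking, collapse alerts,
chemical-space projection and static report generation.

This is the non-interactive core of a monitoring dashboard: it turns a run
log into a diversity time series, fires threshold alerts ("cluster ratio has
been below 0.2 for 5 consecutive steps"), projects fingerprints to 2D and
renders a self-contained HTML report with per-metric plots and
flagged-pattern tables.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_io import MetricConfig, RunLog
from .diversity_metrics import DiversityTimeSeries, Fingerprint, compute_all

__all__ = [
    "AlertRule",
    "Projection2D",
    "track_run",
    "check_alerts",
    "write_alerts",
    "project_2d",
    "render_report",
]


def track_run(log: RunLog, config: MetricConfig | None = None) -> DiversityTimeSeries:
    """Compute every enabled metric for every step of a run log.

    Adds ``mean_score`` and ``mean_nll`` per step when scores / prior
    negative log-likelihoods are present in the log.
    """
    if len(log) == 0:
        raise ValueError("track_run requires a non-empty log")
    config = config or MetricConfig()
    series = DiversityTimeSeries()
    for step in log:
        values = compute_all(step, config)
        scores = [r.score for r in step.records if r.score is not None]
        if scores:
            values["mean_score"] = float(np.mean(scores))
        nlls = [r.nll for r in step.records if r.nll is not None]
        if nlls:
            values["mean_nll"] = float(np.mean(nlls))
        series.append(step.step, values)
    return series


# ---------------------------------------------------------------------------
# Alerts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlertRule:
    """Fire when a metric sits on the wrong side of a threshold for
    ``patience`` consecutive steps (collapse detection)."""

    metric: str
    direction: Literal["above", "below"]
    threshold: float
    patience: int = 5

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")


def check_alerts(
    series: DiversityTimeSeries, rules: Sequence[AlertRule]
) -> list[tuple[AlertRule, int]]:
    """First firing step of each rule that fires (at most one firing per rule).

    A rule fires at the last step of the first window of ``patience``
    consecutive steps all on the wrong side of the threshold.
    """
    firings: list[tuple[AlertRule, int]] = []
    for rule in rules:
        steps, values = series.series(rule.metric)  # KeyError on unknown metric
        run = 0
        for s, v in zip(steps, values):
            bad = v > rule.threshold if rule.direction == "above" else v < rule.threshold
            run = run + 1 if bad else 0
            if run >= rule.patience:
                firings.append((rule, s))
                break
    return firings


def write_alerts(path: str | Path, firings: Sequence[tuple[AlertRule, int]]) -> None:
    rows = [
        {
            "metric": rule.metric,
            "direction": rule.direction,
            "threshold": rule.threshold,
            "patience": rule.patience,
            "fired_step": step,
        }
        for rule, step in firings
    ]
    pd.DataFrame(
        rows, columns=["metric", "direction", "threshold", "patience", "fired_step"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 2D projection
# ---------------------------------------------------------------------------


@dataclass
class Projection2D:
    """Per-molecule 2D coordinates from a dimensionality reduction."""

    method: Literal["pca", "tsne", "umap"]
    coordinates: np.ndarray  # (n, 2)
    seed: int
    explained_variance: tuple[float, float] | None = None  # pca only


def _fingerprint_matrix(fingerprints: Sequence[Fingerprint]) -> np.ndarray:
    x = np.zeros((len(fingerprints), len(fingerprints[0])), dtype=float)
    for i, fp in enumerate(fingerprints):
        for b in fp.bits.GetOnBits():
            x[i, b] = 1.0
    return x


def _pca_2d(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Top-2 principal components via eigendecomposition of the covariance.

    Sign convention: each component's largest-magnitude loading is positive,
    so the projection is deterministic and order-independent up to ties.
    """
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / max(len(x) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:2]
    components = eigvecs[:, order]  # (d, 2)
    for k in range(2):
        lead = np.argmax(np.abs(components[:, k]))
        if components[lead, k] < 0:
            components[:, k] = -components[:, k]
    coords = centered @ components
    total = eigvals.sum()
    explained = eigvals[order] / total if total > 0 else np.zeros(2)
    return coords, (float(explained[0]), float(explained[1]))


def project_2d(
    fingerprints: Sequence[Fingerprint],
    method: Literal["pca", "tsne", "umap"] = "pca",
    seed: int = 0,
) -> Projection2D:
    """Project fingerprints to 2D.

    PCA is implemented in-house and is fully deterministic; t-SNE and UMAP
    are delegated to scikit-learn / umap-learn with a fixed seed (stochastic
    embeddings — treat as exploratory, not assertable).
    """
    if len(fingerprints) < 3:
        raise ValueError(f"need at least 3 molecules to project, got {len(fingerprints)}")
    x = _fingerprint_matrix(fingerprints)
    if method == "pca":
        coords, explained = _pca_2d(x)
        return Projection2D(method="pca", coordinates=coords, seed=seed, explained_variance=explained)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (len(x) - 1) / 3)
        coords = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca").fit_transform(x)
        return Projection2D(method="tsne", coordinates=np.asarray(coords), seed=seed)
    if method == "umap":
        import umap

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(x)
        return Projection2D(method="umap", coordinates=np.asarray(coords), seed=seed)
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# Static report
# ---------------------------------------------------------------------------


def _plot_metric_png(steps: list[int], values: list[float], name: str) -> str:
    """Render one metric trajectory to a base64 PNG (embeds in the HTML)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 2.6), dpi=90)
    ax.plot(steps, values, lw=1.2)
    ax.set_xlabel("step")
    ax.set_ylabel(name)
    ax.set_title(name, fontsize=9)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def render_report(
    series: DiversityTimeSeries,
    flagged: Sequence[dict] = (),
    projection: Projection2D | None = None,
    out_path: str | Path = "report.html",
    figures_dir: str | Path | None = None,
) -> Path:
    """Write a self-contained static HTML report.

    One temporal plot per metric, the flagged-pattern table (present even
    when empty) and an optional projection panel.  The numeric tables are
    exactly the long-format metrics CSV content, so regeneration on the same
    inputs is byte-stable.
    """
    if len(series) == 0:
        raise ValueError("render_report requires a non-empty series")
    out_path = Path(out_path)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Diversity report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 8px;font-size:12px}</style>",
        "</head><body><h1>Chemical diversity report</h1>",
        "<h2>Metric trajectories</h2>",
    ]
    for name in series.metric_names():
        steps, values = series.series(name)
        png = _plot_metric_png(steps, values, name)
        parts.append(f"<img alt='{name}' src='data:image/png;base64,{png}'/>")
        if figures_dir is not None:
            figdir = Path(figures_dir)
            figdir.mkdir(parents=True, exist_ok=True)
            (figdir / f"{name}.png").write_bytes(base64.b64decode(png))
    parts.append("<h2>Metric values</h2>")
    parts.append(series.to_frame().to_html(index=False, float_format="%.17g"))
    parts.append("<h2>Flagged patterns</h2>")
    flagged_df = pd.DataFrame(
        list(flagged),
        columns=["pattern_type", "pattern", "first_step", "occurrences", "frequency"],
    )
    parts.append(flagged_df.to_html(index=False, float_format="%.17g"))
    if projection is not None:
        parts.append(f"<h2>Chemical space projection ({projection.method})</h2>")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4), dpi=90)
        ax.scatter(projection.coordinates[:, 0], projection.coordinates[:, 1], s=8, alpha=0.6)
        ax.set_xlabel("component 1")
        ax.set_ylabel("component 2")
        if projection.explained_variance:
            ax.set_title(
                "explained variance: "
                f"{projection.explained_variance[0]:.2f}, {projection.explained_variance[1]:.2f}",
                fontsize=9,
            )
        fig.tight_layout()
        buf = io.BytesIO()
        fig.savefig(buf, format="png")
        plt.close(fig)
        png = base64.b64encode(buf.getvalue()).decode("ascii")
        parts.append(f"<img alt='projection' src='data:image/png;base64,{png}'/>")
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts))
    return out_path
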