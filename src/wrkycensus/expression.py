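"""Qualitative expression-pattern calls from gene × sample matrices.

The census reports expression qualitatively: which tissues a gene is
detected in, how it behaves across fruit developmental stages (days
after flowering, DAF), and whether hormone/sugar treatments induce or
repress it relative to paired controls.  This module turns nonnegative
expression matrices (RNA-seq abundances or qPCR-derived values) plus a
sample-metadata table into those calls.

Sample metadata columns: ``sample`` (matrix column id), ``tissue``,
``stage`` (DAF integer or empty), ``treatment`` (``none``/IAA/ABA/
sucrose), ``control_pair`` (sample id of the paired control, empty for
untreated samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREND_LABELS = ("up", "down", "flat", "mixed")
RESPONSE_LABELS = ("induced", "repressed", "unchanged", "undetected")


@dataclass
class ExpressionData:
    """Matrix (genes × samples) plus per-sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        meta = self.metadata.set_index("sample") if "sample" in self.metadata.columns \
            else self.metadata
        missing = set(self.values.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        meta = meta.copy()
        if "stage" in meta.columns:
            meta["stage"] = pd.to_numeric(meta["stage"], errors="coerce")
        if "treatment" in meta.columns:
            meta["treatment"] = meta["treatment"].fillna("none").replace("", "none")
        self.metadata = meta

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path) -> "ExpressionData":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
        return cls(values, meta)


@dataclass
class ExpressionCall:
    gene_id: str
    expressed_tissues: set[str]
    trend: str | None
    responses: dict[tuple[str, int], str] = field(default_factory=dict)


def call_expressed(
    data: ExpressionData, threshold: float = 0.0, tissues: list[str] | None = None
) -> dict[str, set[str]]:
    """Tissues in which each gene exceeds the detection threshold.

    A gene counts as expressed in a tissue when its maximum over that
    tissue's untreated samples is > ``threshold``.
    """
    meta = data.metadata
    untreated = meta[meta.get("treatment", "none").fillna("none").isin(["none", ""])]
    available = [t for t in untreated["tissue"].dropna().unique() if t]
    if tissues is not None:
        unknown = set(tissues) - set(available)
        if unknown:
            raise ValueError(f"unknown tissues: {sorted(unknown)}")
    else:
        tissues = sorted(available)
    out: dict[str, set[str]] = {}
    for gene in data.values.index:
        row = data.values.loc[gene]
        expressed = set()
        for tissue in tissues:
            cols = untreated.index[untreated["tissue"] == tissue]
            cols = [c for c in cols if c in row.index]
            if cols and row[cols].max() > threshold:
                expressed.add(tissue)
        out[gene] = expressed
    return out


def stage_series(data: ExpressionData, tissue: str = "fruit") -> pd.DataFrame:
    """Per-stage mean expression (untreated samples of one tissue),
    columns ordered by increasing stage."""
    meta = data.metadata
    controls = set(meta.get("control_pair", pd.Series(dtype=str)).dropna()) - {""}
    mask = (
        (meta["tissue"] == tissue)
        & meta.get("treatment", "none").fillna("none").isin(["none", ""])
        & meta["stage"].notna()
        & ~meta.index.isin(controls)
    )
    staged = meta[mask]
    stages = sorted(staged["stage"].astype(int).unique())
    series = {}
    for stage in stages:
        cols = staged.index[staged["stage"].astype(int) == stage]
        series[stage] = data.values[list(cols)].mean(axis=1)
    return pd.DataFrame(series)


def devel_trend(
    series: pd.DataFrame, min_fold: float = 2.0, tolerance: float = 0.0
) -> dict[str, str]:
    """Trend label per gene across ordered developmental stages.

    up: last/first >= min_fold and the series is non-decreasing within
    the relative tolerance; down: symmetric; flat: max/min < min_fold;
    anything else: mixed.  A zero first stage with positive later
    signal is treated as an infinite fold (logged).
    """
    if series.shape[1] < 2:
        raise ValueError("trend analysis needs >= 2 stages")
    stages = list(series.columns)
    if stages != sorted(stages):
        raise ValueError("stages must be strictly increasing")
    out = {}
    for gene, row in series.iterrows():
        v = row.to_numpy(dtype=float)
        first, last = v[0], v[-1]
        vmax, vmin = v.max(), v.min()
        if vmax <= 0:
            out[gene] = "flat"
            continue
        if vmin > 0 and vmax / vmin < min_fold:
            out[gene] = "flat"
            continue
        nondecreasing = all(b >= a * (1.0 - tolerance) for a, b in zip(v, v[1:]))
        nonincreasing = all(b <= a * (1.0 + tolerance) for a, b in zip(v, v[1:]))
        up_fold = (first == 0 and last > 0) or (first > 0 and last / first >= min_fold)
        down_fold = (last == 0 and first > 0) or (last > 0 and first / last >= min_fold)
        if first == 0 and last > 0:
            logger.info("gene %s: zero baseline, infinite fold", gene)
        if up_fold and nondecreasing:
            out[gene] = "up"
        elif down_fold and nonincreasing:
            out[gene] = "down"
        else:
            out[gene] = "mixed"
    return out


def treatment_response(
    data: ExpressionData, fold: float = 2.0, detection_threshold: float = 0.0
) -> dict[str, dict[tuple[str, int], str]]:
    """Induced/repressed/unchanged/undetected per treated sample.

    Keys of the inner mapping are (treatment, stage).  Raises when a
    treated sample lacks its paired control.
    """
    meta = data.metadata
    treated = meta[~meta.get("treatment", "none").fillna("none").isin(["none", ""])]
    out: dict[str, dict[tuple[str, int], str]] = {
        g: {} for g in data.values.index
    }
    for sample, row in treated.iterrows():
        control = row.get("control_pair")
        if not isinstance(control, str) or not control or control not in data.values.columns:
            raise ValueError(f"treated sample {sample} has no paired control")
        key = (row["treatment"], int(row["stage"]))
        t_vals = data.values[sample]
        c_vals = data.values[control]
        for gene in data.values.index:
            t, c = float(t_vals[gene]), float(c_vals[gene])
            if t <= detection_threshold and c <= detection_threshold:
                label = "undetected"
            elif c == 0 or t / c >= fold:
                label = "induced"
            elif t == 0 or c / t >= fold:
                label = "repressed"
            else:
                label = "unchanged"
            out[gene][key] = label
    return out


def ddct_to_fold(delta_delta_ct: float) -> float:
    """qPCR 2^-ΔΔCt conversion to a linear fold change."""
    return 2.0 ** (-delta_delta_ct)


def call_all(
    data: ExpressionData,
    threshold: float = 0.0,
    min_fold: float = 2.0,
    tolerance: float = 0.0,
    trend_tissue: str = "fruit",
) -> list[ExpressionCall]:
    """Full per-gene call set: tissues, trend and treatment responses."""
    expressed = call_expressed(data, threshold)
    try:
        trends = devel_trend(stage_series(data, trend_tissue), min_fold, tolerance)
    except (ValueError, KeyError):
        logger.warning("no usable stage series; trend calls skipped")
        trends = {}
    try:
        responses = treatment_response(data, min_fold, threshold)
    except ValueError:
        logger.warning("no usable treated/control pairing; response calls skipped")
        responses = {}
    return [
        ExpressionCall(
            gene_id=g,
            expressed_tissues=expressed.get(g, set()),
            trend=trends.get(g),
            responses=responses.get(g, {}),
        )
        for g in data.values.index
    ]
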