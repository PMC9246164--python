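"""Functional connectivity (FC) of node time series and lesion impact (IFC).

FC is the matrix of Pearson correlations between the activity time series of
all non-input nodes over one episode.  The impact of a lesion on functional
connectivity (IFC) is the absolute element-wise sum of the difference between
the intact and lesioned FC matrices, computed from a matched pair of episodes
driven by the identical stimulus so the difference is attributable to the
lesion alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .netmodel import (
    ActivityTrace,
    Genome,
    LesionMask,
    ValidationError,
    node_lesion_mask,
    prune_disabled,
    run,
)
from .toytask import TaskSpec, generate_inputs, _score_actions

__all__ = ["FCMatrix", "fc", "ifc", "ifc_sweep", "correlate_ifc"]


@dataclass
class FCMatrix:
    """Symmetric Pearson-correlation matrix over node pairs.

    Zero-variance (silenced) series cannot be correlated; their rows, columns
    and diagonal entries are filled with 0 and the node is flagged in
    ``degenerate`` rather than propagating NaNs.
    """

    matrix: pd.DataFrame
    degenerate: tuple[int, ...] = ()

    @property
    def node_ids(self) -> list:
        return list(self.matrix.index)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.matrix.loc[i, j])


def fc(trace: ActivityTrace) -> FCMatrix:
    """Pearson functional connectivity of an activity trace (T >= 2)."""
    values = np.asarray(trace.values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("FC needs at least 2 timesteps")
    sd = values.std(axis=0)
    degenerate = [nid for nid, s in zip(trace.node_ids, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(values, rowvar=False)
    m = np.atleast_2d(m)
    bad = sd == 0.0
    m[bad, :] = 0.0
    m[:, bad] = 0.0
    m = np.clip(m, -1.0, 1.0)
    df = pd.DataFrame(m, index=list(trace.node_ids), columns=list(trace.node_ids))
    return FCMatrix(df, tuple(degenerate))


def ifc(fc_intact: FCMatrix, fc_lesioned: FCMatrix) -> float:
    """Absolute element-wise sum of the FC difference matrix (>= 0).

    Sums over the full matrix, i.e. both symmetric triangles (and the zero
    diagonal difference), so a single changed correlation contributes twice.
    """
    if list(fc_intact.node_ids) != list(fc_lesioned.node_ids):
        raise ValidationError("FC matrices cover different node sets")
    diff = fc_intact.matrix.to_numpy() - fc_lesioned.matrix.to_numpy()
    return float(np.abs(diff).sum())


def ifc_sweep(
    genome: Genome,
    task: TaskSpec,
    granularity: str = "nodes",
) -> pd.DataFrame:
    """Single-site lesion sweep of IFC and performance.

    Runs one intact reference episode on the stimulus defined by ``task``,
    then re-runs the identical stimulus under each single-element lesion;
    reports per element the IFC against the intact FC and the episode score.
    Deterministic given ``task.seed``.
    """
    genome = prune_disabled(genome)
    if granularity == "nodes":
        elements = [n.id for n in genome.nodes]
        masks = {e: node_lesion_mask(genome, e) for e in elements}
    elif granularity == "connections":
        elements = list(genome.connection_keys())
        masks = {
            e: LesionMask(disabled_connections=frozenset({e})) for e in elements
        }
    else:
        raise ValidationError(f"unknown granularity {granularity!r}")
    series = generate_inputs(task, n_inputs=len(genome.input_ids))
    trace0, actions0 = run(genome, series)
    fc0 = fc(trace0)
    rows = []
    for e in elements:
        trace, actions = run(genome, series, masks[e])
        rows.append(
            {
                "element": str(e),
                "ifc": ifc(fc0, fc(trace)),
                "score": float(_score_actions(np.asarray(actions), task)),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["intact_score"] = float(_score_actions(np.asarray(actions0), task))
    return df


def correlate_ifc(table: pd.DataFrame, values) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of IFC against a per-element
    quantity (performance, Shapley value, ...), aligned by position."""
    x = np.asarray(table["ifc"], dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValidationError("length mismatch between IFC table and values")
    if x.size < 3:
        raise ValidationError("need at least 3 elements to correlate")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("degenerate (constant) vector in correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
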