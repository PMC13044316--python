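"""Per-cell clustering index: the proportion of vesicles in direct contact.

The headline statistic is, for each cell, the fraction of its segmented
vesicles that touch at least one other vesicle of the same cell.  "Touching"
follows the adjacent-objects convention of CellProfiler's neighbor
measurement: two labels are neighbors when their pixel supports, each
expanded by ``expand_px`` with an 8-connected structuring element, overlap —
equivalently when the minimum Chebyshev distance between the supports is at
most ``2 * expand_px`` (or 1 at ``expand_px == 0``, plain 8-connectivity).

Contacts across cell boundaries are discarded: the proportion is computed
"for each cell", so a vesicle touching only a neighboring cell's vesicle
counts as non-contacting.  Cells with fewer than two assigned vesicles have
an undefined index and are excluded from condition means.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi


UNASSIGNED = 0  # cell id for vesicles whose centroid falls on background


def assign_to_cells(vesicle_mask: np.ndarray,
                    cell_mask: np.ndarray) -> dict[int, int]:
    """Map each vesicle label to the cell containing its centroid.

    The centroid is rounded to the nearest pixel; a centroid on background
    maps to :data:`UNASSIGNED` and the vesicle is excluded downstream.
    """
    vesicle_mask = np.asarray(vesicle_mask)
    cell_mask = np.asarray(cell_mask)
    if vesicle_mask.shape != cell_mask.shape:
        raise ValueError("vesicle and cell masks must have the same shape")
    labels = np.unique(vesicle_mask[vesicle_mask > 0])
    if len(labels) == 0:
        return {}
    centroids = ndi.center_of_mass(vesicle_mask > 0, vesicle_mask, labels)
    out: dict[int, int] = {}
    for lab, (cy, cx) in zip(labels, centroids):
        iy = min(max(int(round(cy)), 0), cell_mask.shape[0] - 1)
        ix = min(max(int(round(cx)), 0), cell_mask.shape[1] - 1)
        out[int(lab)] = int(cell_mask[iy, ix])
    return out


def _chebyshev_threshold(expand_px: int) -> int:
    # expanding both objects by e px makes them overlap iff the original
    # Chebyshev gap is <= 2e; at e=0 plain 8-connectivity means distance <= 1
    return 2 * expand_px if expand_px > 0 else 1


def build_adjacency(vesicle_mask: np.ndarray, expand_px: int = 1) -> nx.Graph:
    """Undirected contact graph over vesicle labels.

    Labels i != j are connected iff the minimum Chebyshev distance between
    their pixel sets is at most ``2 * expand_px`` (1 for ``expand_px == 0``).
    The default of 1 px means "touching or separated by one background
    pixel", absorbing the one-pixel erosion jitter of segmentation.
    """
    if expand_px < 0:
        raise ValueError("expand_px must be >= 0")
    mask = np.asarray(vesicle_mask)
    t = _chebyshev_threshold(expand_px)
    g = nx.Graph()
    labels = np.unique(mask[mask > 0])
    g.add_nodes_from(int(x) for x in labels)

    slices = ndi.find_objects(mask)
    h, w = mask.shape
    for lab in labels:
        sl = slices[lab - 1]
        y0 = max(sl[0].start - t, 0)
        y1 = min(sl[0].stop + t, h)
        x0 = max(sl[1].start - t, 0)
        x1 = min(sl[1].stop + t, w)
        win = mask[y0:y1, x0:x1]
        own = win == lab
        # Chebyshev ball of radius t == square structuring element
        grown = ndi.binary_dilation(own, structure=np.ones((3, 3), bool),
                                    iterations=t)
        for other in np.unique(win[grown & (win != lab) & (win > 0)]):
            g.add_edge(int(lab), int(other))
    return g


def clustering_index(graph: nx.Graph, assignment: dict[int, int], *,
                     condition: str = "", experiment_id: str = ""
                     ) -> pd.DataFrame:
    """Per-cell clustering index table from the contact graph.

    Returns one row per cell: ``condition, experiment, cell, n_vesicles,
    n_contacting, index``.  Inter-cell edges are ignored; cells with fewer
    than two assigned vesicles get ``index = NaN`` (undefined).
    """
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"graph nodes missing from assignment: {missing[:5]}")
    cells = sorted({c for c in assignment.values() if c != UNASSIGNED})
    rows = []
    for cell in cells:
        members = [v for v, c in assignment.items() if c == cell]
        n = len(members)
        member_set = set(members)
        contacting = sum(
            1 for v in members
            if any(nb in member_set for nb in graph.neighbors(v))
        )
        rows.append({
            "condition": condition, "experiment": experiment_id, "cell": cell,
            "n_vesicles": n, "n_contacting": contacting if n >= 2 else 0,
            "index": contacting / n if n >= 2 else np.nan,
        })
    return pd.DataFrame(rows, columns=["condition", "experiment", "cell",
                                       "n_vesicles", "n_contacting", "index"])


def quantify_scene(vesicle_mask: np.ndarray, cell_mask: np.ndarray, *,
                   expand_px: int = 1, condition: str = "",
                   experiment_id: str = "") -> pd.DataFrame:
    """Convenience wrapper: assignment + adjacency + per-cell index."""
    assignment = assign_to_cells(vesicle_mask, cell_mask)
    graph = build_adjacency(vesicle_mask, expand_px=expand_px)
    return clustering_index(graph, assignment, condition=condition,
                            experiment_id=experiment_id)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Condition means by the superplot convention.

    Per-cell indices are averaged within each experiment, then experiment
    means are averaged (unweighted) within each condition.
    """
    defined = table.dropna(subset=["index"])
    per_exp = (defined.groupby(["condition", "experiment"], sort=True)["index"]
               .mean().rename("experiment_mean").reset_index())
    per_cond = (per_exp.groupby("condition", sort=True)["experiment_mean"]
                .agg(mean="mean", sd="std", n_experiments="count")
                .reset_index())
    return per_cond
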