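"""Dual-color signal decoding.

Per-channel spots are turned into marker calls by colocalization within each
color code, false positives are filtered (single-channel spots, off-code
combinations, groups spanning more than four channels), a two-level masking
hierarchy suppresses spurious multi-decoding in dense areas, and accepted
signals are assigned to segmented cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook
from .segmentation import adaptive_mask, CellLabelMap

__all__ = [
    "DecodedSignal",
    "STATUS_ACCEPTED",
    "colocalize_code",
    "decode_signals",
    "apply_masks",
    "autofluorescence_objects",
    "apply_artifact_masks",
    "assign_to_cells",
    "signals_to_frame",
]

STATUS_ACCEPTED = "accepted"
#: Channel-span size above which a colocalization group is unspecific.
UNSPECIFIC_SPAN = 4  # "> 4 channels"

#: Masking hierarchy: level 1 masks AR-FL with high-expression structural
#: markers; level 2 masks the remaining low-expression markers.
MASK_LEVELS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("VIM", "KRT"), ("AR-FL",)),
    (("VIM", "KRT", "AR-FL", "PSA"), ("EPCAM", "PSMA", "AR-V7", "NE", "SLFN11", "DLL3")),
)


@dataclass(frozen=True)
class DecodedSignal:
    """One decoding outcome: a marker call or a rejected/masked candidate."""

    marker: str | None
    x: float
    y: float
    spot_ids: tuple[int, ...]
    status: str = STATUS_ACCEPTED
    cell_id: int | None = None

    @property
    def accepted(self) -> bool:
        return self.status == STATUS_ACCEPTED


def colocalize_code(
    spots: pd.DataFrame, code: tuple[str, str], radius: float
) -> list[tuple[int, int, float]]:
    """One-to-one pairing of spots across the two channels of a code.

    Greedy by ascending distance (ties broken by (y, x) of each member);
    only pairs within ``radius`` qualify.  Returns (index_a, index_b,
    distance) triples referring to row indices of ``spots``.
    """
    if radius <= 0:
        raise ValueError("colocalization radius must be positive")
    ch_a, ch_b = sorted(code)
    a = spots[spots["channel"] == ch_a]
    b = spots[spots["channel"] == ch_b]
    if a.empty or b.empty:
        return []

    tree = cKDTree(b[["y", "x"]].to_numpy(float))
    candidates = []
    for ia, row in a.iterrows():
        for jb in tree.query_ball_point([row["y"], row["x"]], radius):
            ib = b.index[jb]
            d = float(np.hypot(row["y"] - b.at[ib, "y"], row["x"] - b.at[ib, "x"]))
            candidates.append((d, row["y"], row["x"], b.at[ib, "y"], b.at[ib, "x"], ia, ib))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, _, _, _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((int(ia), int(ib), d))
    return pairs


def _link_groups(spots: pd.DataFrame, radius: float) -> np.ndarray:
    """Single-linkage grouping of all spots within ``radius`` (union-find)."""
    n = len(spots)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    coords = spots[["y", "x"]].to_numpy(float)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    return np.array([find(i) for i in range(n)])


def decode_signals(
    spots: pd.DataFrame, cb: Codebook, radius: float = 2.5
) -> list[DecodedSignal]:
    """Decode per-channel spots into marker calls.

    Every marker code is colocalized independently, so a spot shared by two
    overlapping transcripts can contribute to several candidates (the masking
    hierarchy arbitrates).  Spots in no pair become ``rejected_single_channel``
    if isolated in their channel, or part of a ``rejected_off_code`` group if
    their colocalization group spans 2-4 channels but contains no usable code.
    Groups spanning more than 4 channels are unspecific.
    """
    spots = spots.reset_index(drop=True)
    signals: list[DecodedSignal] = []
    if spots.empty:
        return signals

    group_of = _link_groups(spots, radius)
    span_of_group: dict[int, set[str]] = {}
    for i, g in enumerate(group_of):
        span_of_group.setdefault(int(g), set()).add(spots.at[i, "channel"])

    paired: set[int] = set()
    for marker in cb.markers:
        for ia, ib, _ in colocalize_code(spots, marker.code.pair, radius):
            group = int(group_of[ia])
            unspecific = len(span_of_group[group]) > UNSPECIFIC_SPAN
            signals.append(
                DecodedSignal(
                    marker=marker.name,
                    x=float((spots.at[ia, "x"] + spots.at[ib, "x"]) / 2),
                    y=float((spots.at[ia, "y"] + spots.at[ib, "y"]) / 2),
                    spot_ids=(ia, ib),
                    status="unspecific_multichannel" if unspecific else STATUS_ACCEPTED,
                )
            )
            paired.update((ia, ib))

    groups_with_candidates = {int(group_of[i]) for i in paired}
    handled_groups: set[int] = set()
    for i in range(len(spots)):
        if i in paired:
            continue
        group = int(group_of[i])
        span = span_of_group[group]
        if len(span) > UNSPECIFIC_SPAN:
            signals.append(
                DecodedSignal(
                    marker=None,
                    x=float(spots.at[i, "x"]),
                    y=float(spots.at[i, "y"]),
                    spot_ids=(i,),
                    status="unspecific_multichannel",
                )
            )
        elif len(span) >= 2 and group not in groups_with_candidates:
            if group in handled_groups:
                continue
            handled_groups.add(group)
            members = tuple(int(j) for j in np.flatnonzero(group_of == group))
            signals.append(
                DecodedSignal(
                    marker=None,
                    x=float(spots.loc[list(members), "x"].mean()),
                    y=float(spots.loc[list(members), "y"].mean()),
                    spot_ids=members,
                    status="rejected_off_code",
                )
            )
        else:
            signals.append(
                DecodedSignal(
                    marker=None,
                    x=float(spots.at[i, "x"]),
                    y=float(spots.at[i, "y"]),
                    spot_ids=(i,),
                    status="rejected_single_channel",
                )
            )
    return signals


def apply_masks(signals: list[DecodedSignal], radius: float = 2.5) -> list[DecodedSignal]:
    """Apply the two-level masking hierarchy.

    A masker is any signal of a masking marker whose spots are physically
    present: status ``accepted`` or already ``masked_by:*`` (a level-1-masked
    AR-FL still masks level-2 targets).  Idempotent; never increases the
    accepted count.
    """
    out = list(signals)
    for maskers, targets in MASK_LEVELS:
        sources = [
            s
            for s in out
            if s.marker in maskers and (s.accepted or s.status.startswith("masked_by:"))
        ]
        if not sources:
            continue
        tree = cKDTree([(s.y, s.x) for s in sources])
        for idx, sig in enumerate(out):
            if sig.status != STATUS_ACCEPTED or sig.marker not in targets:
                continue
            hits = tree.query_ball_point([sig.y, sig.x], radius)
            if hits:
                nearest = min(
                    hits, key=lambda h: np.hypot(sources[h].y - sig.y, sources[h].x - sig.x)
                )
                out[idx] = replace(sig, status=f"masked_by:{sources[nearest].marker}")
    return out


def autofluorescence_objects(
    bg_a: np.ndarray,
    bg_b: np.ndarray,
    window: int = 64,
    correction: float = 1.0,
    lower_bound: float = 0.0,
    dilation: int = 3,
) -> np.ndarray:
    """Mask of objects bright in *both* background-scan channels.

    For cell samples the two channels are the Cy5 and TexasRed background
    scans; tissue mode uses Atto425 and Atto488 instead.
    """
    from scipy import ndimage as ndi

    a = np.asarray(bg_a, float)
    b = np.asarray(bg_b, float)
    if a.shape != b.shape:
        raise ValueError("background channels must share a shape")
    mask_a = adaptive_mask(a, window=window, correction=correction, lower_bound=lower_bound)
    mask_b = adaptive_mask(b, window=window, correction=correction, lower_bound=lower_bound)
    both = mask_a & mask_b
    if dilation > 0 and both.any():
        both = ndi.binary_dilation(both, iterations=dilation)
    return both


def apply_artifact_masks(
    signals: list[DecodedSignal],
    autofluor_mask: np.ndarray | None = None,
    validity_mask: np.ndarray | None = None,
) -> list[DecodedSignal]:
    """Mask accepted signals inside autofluorescent objects or border voids."""
    out = []
    for sig in signals:
        if sig.status == STATUS_ACCEPTED:
            r, c = int(round(sig.y)), int(round(sig.x))
            shape = (
                autofluor_mask.shape if autofluor_mask is not None
                else validity_mask.shape if validity_mask is not None
                else None
            )
            if shape is not None:
                r = min(max(r, 0), shape[0] - 1)
                c = min(max(c, 0), shape[1] - 1)
            if validity_mask is not None and not validity_mask[r, c]:
                sig = replace(sig, status="masked_border")
            elif autofluor_mask is not None and autofluor_mask[r, c]:
                sig = replace(sig, status="masked_autofluor")
        out.append(sig)
    return out


def assign_to_cells(
    signals: list[DecodedSignal], cells: CellLabelMap, markers: tuple[str, ...]
) -> tuple[list[DecodedSignal], pd.DataFrame]:
    """Assign accepted signals to cells and build the per-cell count table.

    Signals on background stay unassigned and contribute no row.  The table
    has one row per cell (all cells in the label map, including zero-count
    ones), one column per marker, and a ``total`` column.
    """
    labels = cells.labels
    assigned: list[DecodedSignal] = []
    counts: dict[int, dict[str, int]] = {
        int(lab): {m: 0 for m in markers} for lab in np.unique(labels) if lab != 0
    }
    for sig in signals:
        if sig.status == STATUS_ACCEPTED and sig.marker is not None:
            r = min(max(int(round(sig.y)), 0), labels.shape[0] - 1)
            c = min(max(int(round(sig.x)), 0), labels.shape[1] - 1)
            lab = int(labels[r, c])
            if lab > 0:
                sig = replace(sig, cell_id=lab)
                counts[lab][sig.marker] += 1
        assigned.append(sig)

    rows = []
    for lab in sorted(counts):
        row = {"cell_id": lab, **counts[lab]}
        row["total"] = int(sum(counts[lab].values()))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["cell_id", *markers, "total"])
    if table.empty:
        table = pd.DataFrame(columns=["cell_id", *markers, "total"])
    return assigned, table


def signals_to_frame(signals: list[DecodedSignal]) -> pd.DataFrame:
    """Flatten decoded signals for CSV export."""
    frame = pd.DataFrame(
        {
            "marker": [s.marker for s in signals],
            "x": pd.Series([s.x for s in signals], dtype=float),
            "y": pd.Series([s.y for s in signals], dtype=float),
            "status": [s.status for s in signals],
            "cell_id": pd.Series(
                [np.nan if s.cell_id is None else s.cell_id for s in signals], dtype=float
            ),
            "n_spots": pd.Series([len(s.spot_ids) for s in signals], dtype=int),
        }
    )
    return frame
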