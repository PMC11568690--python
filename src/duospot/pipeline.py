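"""End-to-end pipeline: ROI detection, registration, segmentation, spot
detection, decoding, masking, and per-cell counting.

Stage order: detect ROIs on the binned nuclear image -> global rigid
pre-alignment (binned, upscaled) -> per-ROI registration refinement ->
background subtraction -> two-pass nucleus segmentation -> cell expansion ->
per-channel spot detection -> dual-color decoding -> masking hierarchy ->
autofluorescence/border masking -> cell assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import decode as dec
from .codebook import Codebook, build_default_panel
from .registration import (
    RigidTransform,
    SamplePair,
    apply_rigid,
    bin_image,
    estimate_rigid,
    scale_transform,
    subtract_background,
)
from .segmentation import (
    CellLabelMap,
    NucleusParams,
    detect_rois,
    expand_cells,
    segment_nuclei,
)
from .spotcall import SpotParams, detect_spots, empty_spot_table

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "run_pipeline_dir"]


@dataclass
class PipelineParams:
    """All tunable stage parameters in one place (YAML-friendly)."""

    mode: str = "cells"  # "cells" | "tissue"
    bin_factor: int = 8
    roi_margin: int = 40
    coloc_radius: float = 2.5
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    spots: SpotParams = field(default_factory=lambda: SpotParams(lower_bound=300.0))
    refine_max_rotation: float = 1.0
    autofluor_channels: tuple[str, str] = ("Cy5", "TexasRed")
    autofluor_lower_bound: float = 150.0
    autofluor_dilation: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "tissue":
            # tissue scans are 2x2 binned and need no background subtraction
            self.bin_factor = 2
            self.autofluor_channels = ("Atto425", "Atto488")


@dataclass
class PipelineResult:
    counts: pd.DataFrame  # one row per cell: cell_id, markers..., total, centroid
    signals: pd.DataFrame  # decoded-signal export
    cell_labels: np.ndarray  # global cell label image
    transform: RigidTransform
    n_rois: int
    manifest: dict


def _match_cells_to_counts(
    cells: CellLabelMap, counts: pd.DataFrame, offset: tuple[int, int]
) -> pd.DataFrame:
    """Attach global centroid coordinates to the per-cell count table."""
    from scipy import ndimage as ndi

    if counts.empty:
        return counts.assign(centroid_y=pd.Series(dtype=float), centroid_x=pd.Series(dtype=float))
    ids = counts["cell_id"].to_numpy()
    centroids = ndi.center_of_mass(np.ones_like(cells.labels), cells.labels, ids)
    counts = counts.copy()
    counts["centroid_y"] = [c[0] + offset[0] for c in centroids]
    counts["centroid_x"] = [c[1] + offset[1] for c in centroids]
    return counts


def run_pipeline(
    pair: SamplePair,
    cb: Codebook | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full decoding pipeline on one sample pair in memory."""
    cb = cb or build_default_panel()
    params = params or PipelineParams()
    nuclear = cb.nuclear_channel
    if nuclear not in pair.original or nuclear not in pair.background:
        raise KeyError(f"both scans must contain the nuclear channel {nuclear!r}")
    for ch in cb.signal_channels:
        if ch not in pair.original:
            raise KeyError(f"original scan is missing channel {ch!r}")
        if params.mode == "cells" and ch not in pair.background:
            raise KeyError(f"background scan is missing channel {ch!r}")

    full_shape = pair.original[nuclear].shape

    # --- global pre-alignment on binned nuclear images ---------------------
    binned_ref = bin_image(pair.original[nuclear], params.bin_factor)
    binned_mov = bin_image(pair.background[nuclear], params.bin_factor)
    t_binned = estimate_rigid(binned_ref, binned_mov)
    t_global = scale_transform(t_binned, params.bin_factor)
    log.info("global transform: %s", t_global.to_json())

    rois = detect_rois(
        binned_ref, params.bin_factor, margin=params.roi_margin, full_shape=full_shape
    )
    markers = cb.marker_names

    # register full-resolution background once; ROIs are cropped from it
    registered_bg: dict[str, np.ndarray] = {}
    global_validity = np.ones(full_shape, bool)
    for ch in pair.background:
        registered_bg[ch], valid = apply_rigid(pair.background[ch], t_global)
        global_validity &= valid

    all_counts: list[pd.DataFrame] = []
    all_signals: list[pd.DataFrame] = []
    global_labels = np.zeros(full_shape, np.int32)
    cell_offset = 0

    for roi in rois:
        r0, c0, r1, c1 = roi.bounds
        orig_crop = {ch: roi.crop(pair.original[ch]) for ch in pair.original}
        bg_crop = {ch: registered_bg[ch][r0:r1, c0:c1] for ch in registered_bg}

        # per-ROI refinement on the nuclear channel
        try:
            t_refine = estimate_rigid(
                orig_crop[nuclear],
                bg_crop[nuclear],
                max_rotation=params.refine_max_rotation,
                angle_tol=0.1,
            )
        except ValueError:
            t_refine = RigidTransform()
        roi_pair = SamplePair(original=orig_crop, background=bg_crop)

        if params.mode == "cells":
            corrected, validity = subtract_background(roi_pair, t_refine, nuclear)
            validity &= global_validity[r0:r1, c0:c1]
        else:
            corrected = {ch: np.asarray(img, float) for ch, img in orig_crop.items()}
            validity = np.ones(orig_crop[nuclear].shape, bool)

        # segmentation on the ROI-masked nuclear image
        dapi = np.where(roi.roi_mask, corrected[nuclear], 0.0)
        nuclei = segment_nuclei(dapi, params.nucleus)
        cells = expand_cells(nuclei)

        # spot detection on subtracted signal channels
        tables = [
            detect_spots(corrected[ch], ch, params.spots) for ch in cb.signal_channels
        ]
        spots = (
            pd.concat([t for t in tables if not t.empty], ignore_index=True)
            if any(not t.empty for t in tables)
            else empty_spot_table()
        )

        signals = dec.decode_signals(spots, cb, params.coloc_radius)
        signals = dec.apply_masks(signals, params.coloc_radius)

        ch_a, ch_b = params.autofluor_channels
        autofluor = dec.autofluorescence_objects(
            registered_bg[ch_a][r0:r1, c0:c1],
            registered_bg[ch_b][r0:r1, c0:c1],
            window=params.spots.window,
            lower_bound=params.autofluor_lower_bound,
            dilation=params.autofluor_dilation,
        )
        signals = dec.apply_artifact_masks(signals, autofluor, validity)

        signals, counts = dec.assign_to_cells(signals, cells, markers)

        # offset to global coordinates / ids
        frame = dec.signals_to_frame(signals)
        frame["x"] += c0
        frame["y"] += r0
        frame["roi_id"] = roi.roi_id
        mask_assigned = frame["cell_id"].notna()
        frame.loc[mask_assigned, "cell_id"] += cell_offset
        all_signals.append(frame)

        counts = _match_cells_to_counts(cells, counts, (r0, c0))
        if not counts.empty:
            counts["cell_id"] += cell_offset
            counts["roi_id"] = roi.roi_id
            all_counts.append(counts)

        region = global_labels[r0:r1, c0:c1]
        place = (cells.labels > 0) & (region == 0)
        region[place] = cells.labels[place] + cell_offset
        cell_offset += int(cells.labels.max())

    counts = (
        pd.concat(all_counts, ignore_index=True)
        if all_counts
        else pd.DataFrame(columns=["cell_id", *markers, "total", "centroid_y", "centroid_x"])
    )
    frames = [f for f in all_signals if not f.empty]
    signals = pd.concat(frames, ignore_index=True) if frames else dec.signals_to_frame([])
    # overlapping ROI boxes can decode the same physical signal in several
    # ROIs; keep one record per (marker, position), preferring the ROI that
    # assigned it to a cell, then the most informative status
    if not signals.empty:
        priority = {"accepted": 0, "masked_autofluor": 2, "masked_border": 3}
        signals = signals.assign(
            _assigned=signals["cell_id"].notna(),
            _prio=signals["status"].map(lambda s: priority.get(s, 1)),
            _xr=signals["x"].round(1),
            _yr=signals["y"].round(1),
        )
        signals = signals.sort_values(
            ["_assigned", "_prio"], ascending=[False, True], kind="stable"
        )
        signals = signals.drop_duplicates(subset=["marker", "_xr", "_yr"])
        signals = signals.drop(columns=["_assigned", "_prio", "_xr", "_yr"])
        signals = signals.sort_values(["y", "x"], kind="stable").reset_index(drop=True)

    manifest = {
        "mode": params.mode,
        "bin_factor": params.bin_factor,
        "coloc_radius": params.coloc_radius,
        "n_rois": len(rois),
        "transform": json.loads(t_global.to_json()),
        "markers": list(markers),
        "seed": params.seed,
    }
    return PipelineResult(
        counts=counts,
        signals=signals,
        cell_labels=global_labels,
        transform=t_global,
        n_rois=len(rois),
        manifest=manifest,
    )


def run_pipeline_dir(
    input_dir,
    output_dir,
    cb: Codebook | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the pipeline on a fixture directory and write standard outputs."""
    from .simgen import read_fixture

    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    original, background = read_fixture(input_dir)
    cb = cb or build_default_panel()
    for ch in (cb.nuclear_channel, *cb.signal_channels):
        if ch not in original:
            raise KeyError(f"input directory is missing original channel {ch!r}")

    pair = SamplePair(original=original, background=background)
    result = run_pipeline(pair, cb, params)

    result.counts.to_csv(output_dir / "cell_counts.csv", index=False)
    result.signals.to_csv(output_dir / "decoded_signals.csv", index=False)
    tifffile.imwrite(
        output_dir / "cell_labels.tif", result.cell_labels.astype(np.uint16)
    )
    with open(output_dir / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return result
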