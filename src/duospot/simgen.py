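"""Synthetic sample generation with full ground truth.

Renders matched original/background multichannel scans — DAPI nuclei in two
intensity tiers, diffraction-limited dual-color coding spots, autofluorescent
multi-channel objects, Cy5->TexasRed bleed-through, and a small rigid
misalignment of the background scan — plus per-cell feature tables drawn from
class-conditional count models, so every downstream stage is testable without
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml

from .codebook import Codebook, NUCLEAR_CHANNEL, build_default_panel
from .registration import RigidTransform

__all__ = [
    "CountModel",
    "SimConfig",
    "GroundTruth",
    "CellTruth",
    "default_count_models",
    "simulate_sample",
    "simulate_feature_table",
    "write_fixture",
    "read_fixture",
    "CLASSES",
    "MARKERS",
]

CLASSES = ("CTC", "PBMC", "artefact", "false_positive", "negative")
MARKERS = ("hem", "VIM", "KRT", "EPCAM", "PSA", "PSMA", "AR-FL", "AR-V7", "NE", "SLFN11", "DLL3")


@dataclass(frozen=True)
class CountModel:
    """Class-conditional per-marker count distribution.

    ``kind`` is one of "nbinom" (mean + size r), "poisson" (mean), or
    "fixed" (degenerate at ``mean``).
    """

    kind: str
    mean: float
    size: float | None = None  # negative-binomial size (dispersion) parameter

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(round(self.mean)), dtype=int)
        if self.kind == "poisson":
            return rng.poisson(self.mean, size=n)
        if self.kind == "nbinom":
            if self.size is None or self.size <= 0:
                raise ValueError("nbinom model requires a positive size parameter")
            p = self.size / (self.size + self.mean)
            return rng.negative_binomial(self.size, p, size=n)
        raise ValueError(f"unknown count model kind {self.kind!r}")


def _poisson_for_positivity(positivity_pct: float) -> CountModel:
    """Poisson model whose P(count >= 1) equals the target positivity."""
    frac = min(max(positivity_pct / 100.0, 0.0), 0.999)
    return CountModel("poisson", float(-np.log1p(-frac)))


def default_count_models() -> dict[tuple[str, str], CountModel]:
    """Per-(class, marker) count models.

    Negative-binomial parameters are tuned so that positivity, median, and
    IQR of the expressed markers match the reported per-class distributions
    (tumor-cell class follows the VCaP-like profile; the blood-cell class the
    PBMC profile).  Markers with median 0 use a Poisson matched to positivity.
    """
    models: dict[tuple[str, str], CountModel] = {}

    ctc = {
        "hem": _poisson_for_positivity(2),
        "VIM": CountModel("nbinom", 2.2, 1.6),
        "KRT": CountModel("nbinom", 6.0, 2.0),
        "EPCAM": CountModel("nbinom", 2.4, 2.0),
        "PSA": CountModel("nbinom", 0.9, 0.7),
        "PSMA": CountModel("nbinom", 5.0, 2.3),
        "AR-FL": CountModel("nbinom", 35.6, 8.5),
        "AR-V7": CountModel("nbinom", 5.0, 1.6),
        "NE": _poisson_for_positivity(12),
        "SLFN11": _poisson_for_positivity(16),
        "DLL3": _poisson_for_positivity(14),
    }
    pbmc = {
        "hem": CountModel("nbinom", 3.6, 1.8),
        "VIM": CountModel("nbinom", 0.65, 0.4),
        "KRT": _poisson_for_positivity(4),
        "EPCAM": CountModel("fixed", 0),
        "PSA": CountModel("fixed", 0),
        "PSMA": _poisson_for_positivity(1),
        "AR-FL": _poisson_for_positivity(1),
        "AR-V7": _poisson_for_positivity(1),
        "NE": _poisson_for_positivity(4),
        "SLFN11": _poisson_for_positivity(7),
        "DLL3": _poisson_for_positivity(1),
    }
    for marker in MARKERS:
        models[("CTC", marker)] = ctc[marker]
        models[("PBMC", marker)] = pbmc[marker]
        models[("negative", marker)] = CountModel("fixed", 0)
        # unspecific signals scattered over all markers
        models[("false_positive", marker)] = CountModel("poisson", 0.5)
        models[("artefact", marker)] = CountModel("poisson", 1.5)
    return models


@dataclass
class SimConfig:
    image_shape: tuple[int, int] = (1024, 1024)
    bin_factor: int = 8
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"CTC": 6, "PBMC": 24, "negative": 10}
    )
    count_model: dict[tuple[str, str], CountModel] = field(default_factory=default_count_models)
    nucleus_radius: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CTC": (28.0, 34.0),
            "PBMC": (10.0, 14.0),
            "negative": (10.0, 14.0),
        }
    )
    spot_sigma: float = 1.2
    spot_amplitude: float = 1500.0
    background_level: float = 100.0
    noise_sd: float = 8.0
    dapi_amplitude_high: tuple[float, float] = (2500.0, 3500.0)
    dapi_amplitude_low: tuple[float, float] = (500.0, 900.0)
    autofluor_rate: int = 3
    autofluor_amplitude: tuple[float, float] = (800.0, 2000.0)
    bleedthrough_beta: float = 0.15
    misalignment: tuple[float, float, float] = (4.0, -3.0, 0.0)  # (dx, dy, theta deg)
    signal_scatter: float = 28.0  # signals land within nucleus_radius + scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bleedthrough_beta < 1:
            raise ValueError("bleedthrough_beta must be in [0, 1)")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if any(n < 0 for n in self.n_cells_per_class.values()):
            raise ValueError("cell counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "bin_factor": self.bin_factor,
            "n_cells_per_class": dict(self.n_cells_per_class),
            "spot_sigma": self.spot_sigma,
            "spot_amplitude": self.spot_amplitude,
            "background_level": self.background_level,
            "noise_sd": self.noise_sd,
            "autofluor_rate": self.autofluor_rate,
            "bleedthrough_beta": self.bleedthrough_beta,
            "misalignment": list(self.misalignment),
            "signal_scatter": self.signal_scatter,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    class_label: str
    centroid: tuple[float, float]  # (y, x)
    radius: float
    dapi_tier: str
    counts: dict[str, int]


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    signals: pd.DataFrame  # columns: marker, x, y, cell_id
    autofluor_objects: list[dict]

    def counts_table(self) -> pd.DataFrame:
        rows = [
            {"cell_id": c.cell_id, "class_label": c.class_label, **c.counts}
            for c in self.cells
        ]
        return pd.DataFrame(rows, columns=["cell_id", "class_label", *MARKERS])


def _place_cells(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, float, float, float]]:
    """Rejection-sample non-overlapping nucleus positions.

    Cells are spaced so that expanded cell regions (nucleus + 12 px) plus the
    signal scatter band never overlap; raises naming the limiting class when
    packing fails.
    """
    h, w = config.image_shape
    placed: list[tuple[str, float, float, float]] = []  # (class, y, x, radius)
    clearance = 12.0 + config.signal_scatter
    for cls in sorted(config.n_cells_per_class):
        n = config.n_cells_per_class[cls]
        if n == 0:
            continue
        if cls not in config.nucleus_radius:
            raise ValueError(f"no nucleus radius configured for class {cls!r}")
        rlo, rhi = config.nucleus_radius[cls]
        for _ in range(n):
            for attempt in range(4000):
                r = rng.uniform(rlo, rhi)
                margin = r + clearance + 4
                y = rng.uniform(margin, h - margin)
                x = rng.uniform(margin, w - margin)
                ok = all(
                    np.hypot(y - py, x - px) > (r + pr + 2 * clearance)
                    for _, py, px, pr in placed
                )
                if ok:
                    placed.append((cls, y, x, r))
                    break
            else:
                raise RuntimeError(
                    f"infeasible packing: could not place cell of class {cls!r} "
                    f"({len(placed)} cells placed in {h}x{w})"
                )
    return placed


def _add_gaussian(img: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    """Add an isotropic Gaussian blob analytically on a local window."""
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(int(y) - half, 0), min(int(y) + half + 1, h)
    c0, c1 = max(int(x) - half, 0), min(int(x) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))


def _add_nucleus(img: np.ndarray, y: float, x: float, radius: float, amp: float) -> None:
    """Radial-falloff disk: full intensity in the core, smooth rim."""
    h, w = img.shape
    half = int(np.ceil(radius + 3))
    r0, r1 = max(int(y) - half, 0), min(int(y) + half + 1, h)
    c0, c1 = max(int(x) - half, 0), min(int(x) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - y, xx - x)
    profile = np.clip(1.0 - (d / radius) ** 4, 0.0, 1.0)
    img[r0:r1, c0:c1] += amp * profile


def simulate_sample(
    config: SimConfig, cb: Codebook | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], GroundTruth]:
    """Render an (original, background) scan pair plus ground truth.

    Every ground-truth signal appears as a Gaussian spot at identical
    coordinates in both channels of its marker's code.  The background scan
    carries nuclei, background level, and autofluorescent objects — but no
    coding spots — and is displaced by ``config.misalignment`` (objects are
    re-rendered analytically at transformed coordinates, so integer,
    rotation-free misalignments are exact).
    """
    cb = cb or build_default_panel()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    channels = (NUCLEAR_CHANNEL,) + tuple(cb.signal_channels)

    placed = _place_cells(config, rng)

    misalign = RigidTransform(
        dx=config.misalignment[0], dy=config.misalignment[1], theta=config.misalignment[2]
    )

    original = {ch: np.zeros((h, w)) for ch in channels}
    background = {ch: np.zeros((h, w)) for ch in channels}

    # --- nuclei (both scans) ---------------------------------------------
    cells: list[CellTruth] = []
    for cell_id, (cls, y, x, radius) in enumerate(placed, start=1):
        tier = "high" if rng.random() < 0.5 else "low"
        lo, hi = (
            config.dapi_amplitude_high if tier == "high" else config.dapi_amplitude_low
        )
        amp = rng.uniform(lo, hi)
        _add_nucleus(original[NUCLEAR_CHANNEL], y, x, radius, amp)
        by, bx = misalign.apply_points([[y, x]], (h, w))[0]
        _add_nucleus(background[NUCLEAR_CHANNEL], by, bx, radius, amp)
        cells.append(
            CellTruth(
                cell_id=cell_id,
                class_label=cls,
                centroid=(y, x),
                radius=radius,
                dapi_tier=tier,
                counts={m: 0 for m in MARKERS},
            )
        )

    # --- coding spots (original scan only) --------------------------------
    code_of = {m.name: m.code.pair for m in cb.markers}
    signal_rows = []
    for cell in cells:
        for marker in cb.marker_names:
            key = (cell.class_label, marker)
            if key not in config.count_model:
                raise KeyError(f"no count model for (class, marker) = {key}")
            count = int(config.count_model[key].sample(rng, 1)[0])
            cell.counts[marker] = count
            cy, cx = cell.centroid
            reach = cell.radius + config.signal_scatter
            for _ in range(count):
                while True:
                    dy, dx_ = rng.uniform(-reach, reach, size=2)
                    if np.hypot(dy, dx_) <= reach:
                        break
                sy, sx = cy + dy, cx + dx_
                amp = config.spot_amplitude * rng.uniform(1.0, 1.2)
                for ch in code_of[marker]:
                    _add_gaussian(original[ch], sy, sx, config.spot_sigma, amp)
                signal_rows.append(
                    {"marker": marker, "x": sx, "y": sy, "cell_id": cell.cell_id}
                )
    signals = pd.DataFrame(signal_rows, columns=["marker", "x", "y", "cell_id"])

    # --- autofluorescent objects (both scans) ------------------------------
    autofluor: list[dict] = []
    for _ in range(int(config.autofluor_rate)):
        for attempt in range(2000):
            y = rng.uniform(30, h - 30)
            x = rng.uniform(30, w - 30)
            if all(
                np.hypot(y - c.centroid[0], x - c.centroid[1])
                > c.radius + config.signal_scatter + 20
                for c in cells
            ):
                break
        else:  # pragma: no cover - pathological configs only
            continue
        radius = rng.uniform(4.0, 8.0)
        chans = {"Cy5", "TexasRed"}
        for ch in cb.signal_channels:
            if ch not in chans and rng.random() < 0.5:
                chans.add(ch)
        amp = rng.uniform(*config.autofluor_amplitude)
        by, bx = misalign.apply_points([[y, x]], (h, w))[0]
        for ch in chans:
            _add_gaussian(original[ch], y, x, radius / 2, amp)
            _add_gaussian(background[ch], by, bx, radius / 2, amp)
        autofluor.append(
            {"y": y, "x": x, "radius": radius, "channels": tuple(sorted(chans))}
        )

    # --- bleed-through, background level, noise ----------------------------
    if config.bleedthrough_beta > 0 and "Cy5" in original and "TexasRed" in original:
        original["TexasRed"] += config.bleedthrough_beta * original["Cy5"]
        background["TexasRed"] += config.bleedthrough_beta * background["Cy5"]

    for ch in channels:
        if ch != NUCLEAR_CHANNEL:
            original[ch] += config.background_level
            background[ch] += config.background_level
        if config.noise_sd > 0:
            original[ch] += rng.normal(0, config.noise_sd, size=(h, w))
            background[ch] += rng.normal(0, config.noise_sd, size=(h, w))
        np.clip(original[ch], 0, 65535, out=original[ch])
        np.clip(background[ch], 0, 65535, out=background[ch])

    truth = GroundTruth(cells=cells, signals=signals, autofluor_objects=autofluor)
    return original, background, truth


def simulate_feature_table(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-cell marker-count rows from the class-conditional models.

    Returns (table, labels); the table has one row per cell with the 11
    marker columns plus ``total``, and class proportions exactly as requested.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    labels = []
    for cls in sorted(config.n_cells_per_class):
        n = config.n_cells_per_class[cls]
        if n == 0:
            continue
        cols = {}
        for marker in MARKERS:
            key = (cls, marker)
            if key not in config.count_model:
                raise KeyError(f"no count model for (class, marker) = {key}")
            cols[marker] = config.count_model[key].sample(rng, n)
        frame = pd.DataFrame(cols)
        frames.append(frame)
        labels.extend([cls] * n)
    if not frames:
        table = pd.DataFrame(columns=[*MARKERS, "total"])
        return table, pd.Series([], dtype=str, name="class_label")
    table = pd.concat(frames, ignore_index=True)
    table["total"] = table[list(MARKERS)].sum(axis=1)
    return table, pd.Series(labels, name="class_label")


def write_fixture(
    original: dict[str, np.ndarray],
    background: dict[str, np.ndarray],
    truth: GroundTruth,
    directory,
    config: SimConfig | None = None,
) -> list[str]:
    """Write a simulated sample to disk in the pipeline's input layout.

    One TIFF per channel per scan under ``original/`` and ``background/``,
    truth tables as CSV, and the config as YAML.  Returns the file manifest.
    """
    from pathlib import Path

    directory = Path(directory)
    manifest: list[str] = []
    for scan_name, scan in (("original", original), ("background", background)):
        sub = directory / scan_name
        sub.mkdir(parents=True, exist_ok=True)
        for ch, img in scan.items():
            path = sub / f"{ch}.tif"
            tifffile.imwrite(path, np.round(img).astype(np.uint16))
            manifest.append(str(path))

    cells_path = directory / "truth_cells.csv"
    truth.counts_table().to_csv(cells_path, index=False)
    manifest.append(str(cells_path))
    signals_path = directory / "truth_signals.csv"
    truth.signals.to_csv(signals_path, index=False)
    manifest.append(str(signals_path))
    if config is not None:
        cfg_path = directory / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        manifest.append(str(cfg_path))
    return manifest


def read_fixture(directory) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a fixture written by :func:`write_fixture`."""
    from pathlib import Path

    directory = Path(directory)
    scans = []
    for scan_name in ("original", "background"):
        sub = directory / scan_name
        scan = {
            p.stem: tifffile.imread(p).astype(float) for p in sorted(sub.glob("*.tif"))
        }
        scans.append(scan)
    return scans[0], scans[1]
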