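"""Strain and morphology measurement from paired pre/post-stretch label masks.

The measurement chain mirrors how stretched-monolayer microscopy is analysed:
the two time points are registered to remove the rigid stage offset, each
nucleus is paired with the cell that contains it, pre-stretch cells are matched
to their post-stretch counterparts, and the nuclear, cytoplasmic and cellular
uniaxial (xx) strains are computed from chord lengths measured along the
stretch axis on the row through the nucleus centroid.

All strains are dimensionless fractions; chord lengths are reported in µm,
morphological features in pixel units (see :func:`compute_morphology`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from scipy.spatial import cKDTree
from skimage.measure import perimeter as _perimeter
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import find_boundaries

logger = logging.getLogger(__name__)

__all__ = [
    "LabelFrame",
    "CellRecord",
    "RegistrationError",
    "read_label_frame",
    "translate_image",
    "register_frames",
    "pair_nucleus_to_cell",
    "match_pre_post",
    "measure_chords",
    "compute_strains",
    "classify_area_change",
    "compute_morphology",
    "morphology_table",
    "measure_pair",
    "MORPHOLOGY_FEATURES",
]


class RegistrationError(RuntimeError):
    """Raised when frame registration cannot be performed (e.g. empty masks)."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass
class LabelFrame:
    """One time point: cell and nucleus label masks plus optional intensity.

    Both masks are integer label images of identical shape (background 0,
    objects labelled with unique positive integers, matched nuclei and cells
    sharing the same label when produced by the synthetic generator).
    ``intensity`` is an optional non-negative image (Hoechst-like nuclear
    signal). ``pixel_size`` is in µm/px.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    intensity: np.ndarray | None = None
    pixel_size: float = 0.25

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask)
        self.nucleus_mask = np.asarray(self.nucleus_mask)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks must share shape")
        if self.cell_mask.min() < 0 or self.nucleus_mask.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.cell_mask.shape:
                raise ValueError("intensity must share mask shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape


@dataclass(frozen=True)
class CellRecord:
    """Chord and nuclear measurements for one paired cell at one time point.

    Chords are measured along the stretch (x = column) axis on the row through
    the nucleus centroid: ``cell_chord`` is the contiguous run of the cell's
    pixels containing the nucleus centroid column, ``nucleus_chord`` the run of
    nucleus pixels on the same row, and ``cytoplasm_chord`` their difference.
    All chords in µm, ``nucleus_area`` in µm².
    """

    cell_id: int
    nucleus_centroid: tuple[float, float]  # (row, col), px
    cell_chord: float
    nucleus_chord: float
    cytoplasm_chord: float
    nucleus_area: float
    intensity_cv: float | None = None


# --------------------------------------------------------------------------- #
# i/o
# --------------------------------------------------------------------------- #


def _read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def read_label_frame(
    cells_path: str | Path,
    nuclei_path: str | Path,
    intensity_path: str | Path | None = None,
    pixel_size: float = 0.25,
) -> LabelFrame:
    """Read a :class:`LabelFrame` from TIFF/PNG mask files."""
    intensity = _read_image(intensity_path) if intensity_path else None
    return LabelFrame(
        cell_mask=_read_image(cells_path).astype(np.int32),
        nucleus_mask=_read_image(nuclei_path).astype(np.int32),
        intensity=intensity,
        pixel_size=pixel_size,
    )


def translate_image(img: np.ndarray, dx: int, dy: int, fill=0) -> np.ndarray:
    """Translate an image by integer (dx, dy) = (columns, rows), zero-filling."""
    out = np.full_like(img, fill)
    h, w = img.shape
    sr0, sr1 = max(0, -dy), min(h, h - dy)
    sc0, sc1 = max(0, -dx), min(w, w - dx)
    dr0, dc0 = max(0, dy), max(0, dx)
    if sr1 > sr0 and sc1 > sc0:
        out[dr0 : dr0 + (sr1 - sr0), dc0 : dc0 + (sc1 - sc0)] = img[sr0:sr1, sc0:sc1]
    return out


def _translate_frame(frame: LabelFrame, dx: int, dy: int) -> LabelFrame:
    return LabelFrame(
        cell_mask=translate_image(frame.cell_mask, dx, dy),
        nucleus_mask=translate_image(frame.nucleus_mask, dx, dy),
        intensity=None
        if frame.intensity is None
        else translate_image(frame.intensity, dx, dy),
        pixel_size=frame.pixel_size,
    )


# --------------------------------------------------------------------------- #
# registration
# --------------------------------------------------------------------------- #


def register_frames(
    pre: LabelFrame, post: LabelFrame, strain_guess: float = 0.0
) -> tuple[tuple[int, int], LabelFrame]:
    """Estimate the rigid (dx, dy) pixel offset of ``post`` relative to ``pre``.

    Phase correlation is run on the cell-boundary images (the binarized cell
    masks of a confluent monolayer are featureless, so label boundaries are
    used as the registration texture). When ``strain_guess`` is non-zero the
    post frame is first unstretched along x about the frame centre so that the
    rigid offset dominates the correlation peak; the recovered x-shift is
    rescaled back to original post coordinates.

    Returns the integer offset ``(dx, dy)`` (columns, rows) such that the post
    frame content sits at ``pre + (dx, dy)``, together with the post frame
    translated by ``(-dx, -dy)``.
    """
    if pre.shape != post.shape:
        raise ValueError("frames must share shape")
    if not pre.cell_mask.any() or not post.cell_mask.any():
        raise RegistrationError("registration failed: empty cell mask")

    feat_pre = find_boundaries(pre.cell_mask, mode="inner").astype(float)
    feat_post = find_boundaries(post.cell_mask, mode="inner").astype(float)
    if strain_guess:
        # output col -> input col: c_in = cx + (1 + s) * (c_out - cx)
        s = 1.0 + strain_guess
        cx = (feat_post.shape[1] - 1) / 2.0
        feat_post = affine_transform(
            feat_post,
            np.diag([1.0, s]),
            offset=[0.0, cx * (1 - s)],
            order=1,
            mode="constant",
        )
    shift, _, _ = phase_cross_correlation(
        feat_pre, feat_post, upsample_factor=1, normalization=None
    )
    # shift = displacement applied to the moving (post) image to reach pre,
    # i.e. -(offset of post relative to pre) in the unstretched geometry.
    dy = int(round(-shift[0]))
    dx = int(round(-shift[1] * (1.0 + strain_guess)))
    logger.info("registered offset (dx, dy) = (%d, %d) px", dx, dy)
    return (dx, dy), _translate_frame(post, -dx, -dy)


# --------------------------------------------------------------------------- #
# pairing and matching
# --------------------------------------------------------------------------- #


def _centroids(mask: np.ndarray) -> dict[int, tuple[float, float]]:
    return {p.label: p.centroid for p in regionprops(mask)}


def pair_nucleus_to_cell(frame: LabelFrame) -> tuple[dict[int, int], dict]:
    """Assign each nucleus label to the cell label covering its centroid.

    Nuclei whose centroid falls on background are assigned by maximal pixel
    overlap; nuclei overlapping no cell are dropped. Cells claimed by two or
    more nuclei are excluded (ambiguous pairing, e.g. mitotic doublets).

    Returns ``(pairing, diagnostics)`` where ``pairing`` maps nucleus label to
    cell label and ``diagnostics`` records dropped/ambiguous counts.
    """
    pairing: dict[int, int] = {}
    dropped: list[int] = []
    for prop in sorted(regionprops(frame.nucleus_mask), key=lambda p: p.label):
        r, c = (int(round(v)) for v in prop.centroid)
        r = min(max(r, 0), frame.shape[0] - 1)
        c = min(max(c, 0), frame.shape[1] - 1)
        cell = int(frame.cell_mask[r, c])
        if cell == 0:
            rr, cc = prop.coords.T
            under = frame.cell_mask[rr, cc]
            under = under[under > 0]
            if under.size == 0:
                dropped.append(prop.label)
                logger.info("nucleus %d overlaps no cell; dropped", prop.label)
                continue
            labels, counts = np.unique(under, return_counts=True)
            # deterministic tie-break: highest overlap, then lowest label
            cell = int(labels[np.lexsort((labels, -counts))[0]])
        pairing[prop.label] = cell

    counts: dict[int, list[int]] = {}
    for nuc, cell in pairing.items():
        counts.setdefault(cell, []).append(nuc)
    ambiguous = sorted(c for c, nucs in counts.items() if len(nucs) > 1)
    for cell in ambiguous:
        logger.info("cell %d paired with %d nuclei; excluded", cell, len(counts[cell]))
        for nuc in counts[cell]:
            del pairing[nuc]
    diagnostics = {"dropped_nuclei": dropped, "ambiguous_cells": ambiguous}
    return pairing, diagnostics


def match_pre_post(
    pre: LabelFrame,
    post: LabelFrame,
    strain_guess: float = 0.25,
) -> dict[int, int]:
    """Match pre-stretch cells to post-stretch cells by mutual nearest centroid.

    Post-stretch centroids are first contracted along x by 1/(1+strain_guess)
    about the frame centre (the stretch axis midpoint) to undo the bulk
    stretch; mutual nearest neighbours in this common geometry define the
    matches. Non-mutual best matches are excluded.
    """
    cen_pre = _centroids(pre.cell_mask)
    cen_post = _centroids(post.cell_mask)
    if not cen_pre or not cen_post:
        return {}
    ids_pre = sorted(cen_pre)
    ids_post = sorted(cen_post)
    a = np.array([cen_pre[i] for i in ids_pre], dtype=float)
    b = np.array([cen_post[i] for i in ids_post], dtype=float)
    cx = (pre.shape[1] - 1) / 2.0
    b = b.copy()
    b[:, 1] = cx + (b[:, 1] - cx) / (1.0 + strain_guess)
    fwd = cKDTree(b).query(a)[1]  # pre -> nearest post
    rev = cKDTree(a).query(b)[1]  # post -> nearest pre
    mapping: dict[int, int] = {}
    for i, j in enumerate(fwd):
        if rev[j] == i:
            mapping[ids_pre[i]] = ids_post[j]
        else:
            logger.debug("cell %d: non-mutual match, excluded", ids_pre[i])
    return mapping


# --------------------------------------------------------------------------- #
# chord measurement and strains
# --------------------------------------------------------------------------- #


def _run_containing(row_values: np.ndarray, label: int, col: int) -> tuple[int, int] | None:
    """Return [start, stop) of the contiguous run of ``label`` containing ``col``."""
    hit = row_values == label
    if not (0 <= col < hit.size) or not hit[col]:
        return None
    start = col
    while start > 0 and hit[start - 1]:
        start -= 1
    stop = col + 1
    while stop < hit.size and hit[stop]:
        stop += 1
    return start, stop


def measure_chords(
    frame: LabelFrame,
    cell_id: int,
    pairing: dict[int, int] | None = None,
) -> CellRecord | None:
    """Measure the mid-line chords for one cell (paired with one nucleus).

    The chord is the contiguous pixel run containing the nucleus centroid, not
    the cell's total occupancy of the row, which makes the measure robust to
    concave cell outlines. Returns ``None`` (with a log entry) for invalid
    records, e.g. when the centroid row intersects no cell pixels.
    """
    if pairing is None:
        pairing = pair_nucleus_to_cell(frame)[0]
    cell_to_nuc = {c: n for n, c in pairing.items()}
    if cell_id not in cell_to_nuc:
        logger.info("cell %d has no paired nucleus; skipped", cell_id)
        return None
    nuc_id = cell_to_nuc[cell_id]
    nuc_props = {p.label: p for p in regionprops(frame.nucleus_mask)}
    prop = nuc_props[nuc_id]
    r_f, c_f = prop.centroid
    row, col = int(round(r_f)), int(round(c_f))
    if not (0 <= row < frame.shape[0]):
        logger.info("cell %d: centroid row outside frame; skipped", cell_id)
        return None

    cell_run = _run_containing(frame.cell_mask[row], cell_id, col)
    if cell_run is None:
        logger.info("cell %d: centroid row has no cell pixels at centroid; skipped", cell_id)
        return None
    nuc_run = _run_containing(frame.nucleus_mask[row], nuc_id, col)
    if nuc_run is None:
        logger.info("cell %d: no nucleus pixels on centroid row; skipped", cell_id)
        return None
    # clip the nucleus run to the cell run so chords are consistent
    n0, n1 = max(nuc_run[0], cell_run[0]), min(nuc_run[1], cell_run[1])
    ps = frame.pixel_size
    l_cell = (cell_run[1] - cell_run[0]) * ps
    l_nuc = max(n1 - n0, 0) * ps
    cv = None
    if frame.intensity is not None:
        rr, cc = prop.coords.T
        vals = frame.intensity[rr, cc]
        mean = float(vals.mean())
        cv = float(vals.std() / mean) if mean > 0 else None
    return CellRecord(
        cell_id=cell_id,
        nucleus_centroid=(r_f, c_f),
        cell_chord=l_cell,
        nucleus_chord=l_nuc,
        cytoplasm_chord=l_cell - l_nuc,
        nucleus_area=prop.area * ps**2,
        intensity_cv=cv,
    )


def compute_strains(pre: CellRecord, post: CellRecord) -> dict | None:
    """Pre/post chord strains for one matched cell.

    ϵ = (L' − L)/L for the nucleus, cytoplasm and whole-cell chords, plus the
    nuclear projected-area change fraction and (when intensity is available)
    the change in within-nucleus intensity coefficient of variation.
    """
    if min(pre.cell_chord, pre.nucleus_chord, pre.cytoplasm_chord) <= 0:
        logger.info("cell %d: zero pre-stretch chord; skipped", pre.cell_id)
        return None
    eps_n = (post.nucleus_chord - pre.nucleus_chord) / pre.nucleus_chord
    eps_c = (post.cytoplasm_chord - pre.cytoplasm_chord) / pre.cytoplasm_chord
    eps_cell = (post.cell_chord - pre.cell_chord) / pre.cell_chord
    da = (post.nucleus_area - pre.nucleus_area) / pre.nucleus_area
    dcv = None
    if pre.intensity_cv is not None and post.intensity_cv is not None:
        dcv = post.intensity_cv - pre.intensity_cv
    return {
        "eps_n": eps_n,
        "eps_c": eps_c,
        "eps_cell": eps_cell,
        "dA_A": da,
        "dCV": dcv,
        "size_class": classify_area_change(da),
    }


def classify_area_change(da_over_a: float) -> str:
    """Classify a nuclear projected-area change: shrink / no_change / expand.

    Shrinkage is an area decrease of at least 1%, expansion an increase of at
    least 1% (both bounds inclusive); anything smaller is no_change.
    """
    if not np.isfinite(da_over_a):
        raise ValueError("area change must be finite")
    if da_over_a <= -0.01:
        return "shrink"
    if da_over_a >= 0.01:
        return "expand"
    return "no_change"


# --------------------------------------------------------------------------- #
# morphology
# --------------------------------------------------------------------------- #

#: 19 morphological features: 9 shape descriptors for the cell and for the
#: nucleus, plus the nucleus-to-cell area ratio. Circularity is area/perimeter²
#: (no 4π factor) and shape index is perimeter/√area.
MORPHOLOGY_FEATURES = tuple(
    f"{who}_{feat}"
    for who in ("cell", "nuc")
    for feat in (
        "perimeter",
        "area",
        "solidity",
        "shape_index",
        "circularity",
        "aspect_ratio",
        "roundness",
        "convex_area",
        "convex_perimeter",
    )
) + ("nuc_cell_area_ratio",)


def _shape_features(prop) -> dict[str, float]:
    area = float(prop.area)
    per = float(prop.perimeter)
    major = float(prop.axis_major_length)
    minor = float(prop.axis_minor_length)
    return {
        "perimeter": per,
        "area": area,
        "solidity": float(prop.solidity),
        "shape_index": per / np.sqrt(area) if area > 0 else np.nan,
        "circularity": area / per**2 if per > 0 else np.nan,
        "aspect_ratio": major / minor if minor > 0 else np.nan,
        "roundness": 4.0 * area / (np.pi * major**2) if major > 0 else np.nan,
        "convex_area": float(prop.area_convex),
        "convex_perimeter": float(_perimeter(prop.image_convex)),
    }


def compute_morphology(
    frame: LabelFrame,
    cell_id: int,
    pairing: dict[int, int] | None = None,
) -> dict | None:
    """Compute the 19-feature morphology vector for one paired cell.

    Features are in pixel units (areas in px², perimeters in px, the remainder
    dimensionless), which keeps them resolution-explicit; the canonical
    correlation analysis standardizes columns so the unit cancels there.
    A ``touches_border`` flag marks cells clipped by the frame edge; flagged
    rows are excluded from CCA.
    """
    if pairing is None:
        pairing = pair_nucleus_to_cell(frame)[0]
    cell_to_nuc = {c: n for n, c in pairing.items()}
    if cell_id not in cell_to_nuc:
        return None
    cell_props = {p.label: p for p in regionprops(frame.cell_mask)}
    nuc_props = {p.label: p for p in regionprops(frame.nucleus_mask)}
    if cell_id not in cell_props:
        return None
    cp = cell_props[cell_id]
    np_ = nuc_props[cell_to_nuc[cell_id]]
    h, w = frame.shape
    r0, c0, r1, c1 = cp.bbox
    touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
    row: dict = {"cell_id": cell_id}
    for key, val in _shape_features(cp).items():
        row[f"cell_{key}"] = val
    for key, val in _shape_features(np_).items():
        row[f"nuc_{key}"] = val
    row["nuc_cell_area_ratio"] = np_.area / cp.area
    row["touches_border"] = bool(touches)
    row["centroid_row"] = cp.centroid[0]
    row["centroid_col"] = cp.centroid[1]
    return row


def morphology_table(frame: LabelFrame) -> pd.DataFrame:
    """Morphology rows for every paired cell of a frame (see compute_morphology)."""
    pairing, _ = pair_nucleus_to_cell(frame)
    rows = []
    for cell_id in sorted({c for c in pairing.values()}):
        row = compute_morphology(frame, cell_id, pairing)
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# end-to-end measurement
# --------------------------------------------------------------------------- #


def _border_labels(mask: np.ndarray) -> set[int]:
    edge = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return set(int(v) for v in np.unique(edge) if v > 0)


def measure_pair(
    pre: LabelFrame,
    post: LabelFrame,
    strain_guess: float = 0.25,
    register: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run register → pair → match → measure on a pre/post frame pair.

    Cells touching the frame edge in either time point are censored (their
    chords are incomplete) and excluded from all tables. Returns the per-cell
    strain table, the pre-stretch morphology table and a diagnostics dict.
    """
    offset = (0, 0)
    # cells clipped by the frame edge must be identified before any
    # registration shift zero-fills the margin and hides them
    border_post = _border_labels(post.cell_mask)
    if register:
        offset, post = register_frames(pre, post, strain_guess=strain_guess)
    border_post |= _border_labels(post.cell_mask)

    pairing_pre, diag_pre = pair_nucleus_to_cell(pre)
    pairing_post, diag_post = pair_nucleus_to_cell(post)
    cells_pre = {c: n for n, c in pairing_pre.items()}
    cells_post = {c: n for n, c in pairing_post.items()}
    mapping = match_pre_post(pre, post, strain_guess=strain_guess)
    border_pre = _border_labels(pre.cell_mask)

    n_border = n_invalid = 0
    rows = []
    for pre_id in sorted(mapping):
        post_id = mapping[pre_id]
        if pre_id not in cells_pre or post_id not in cells_post:
            continue
        if pre_id in border_pre or post_id in border_post:
            n_border += 1
            continue
        rec_pre = measure_chords(pre, pre_id, pairing_pre)
        rec_post = measure_chords(post, post_id, pairing_post)
        if rec_pre is None or rec_post is None:
            n_invalid += 1
            continue
        strains = compute_strains(rec_pre, rec_post)
        if strains is None:
            n_invalid += 1
            continue
        rows.append(
            {
                "cell_id": pre_id,
                "post_id": post_id,
                "L_cell_pre": rec_pre.cell_chord,
                "L_n_pre": rec_pre.nucleus_chord,
                **strains,
            }
        )
    strain_table = pd.DataFrame(rows)
    morph = morphology_table(pre)
    if not morph.empty:
        measured = set(strain_table["cell_id"]) if not strain_table.empty else set()
        morph = morph[morph["cell_id"].isin(measured)].reset_index(drop=True)
    diagnostics = {
        "offset_px": offset,
        "n_matched": len(mapping),
        "n_measured": len(rows),
        "n_border_excluded": n_border,
        "n_invalid": n_invalid,
        "pre_pairing": diag_pre,
        "post_pairing": diag_post,
    }
    return strain_table, morph, diagnostics
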