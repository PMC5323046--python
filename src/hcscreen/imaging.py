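"""Quantification of two-channel well images.

Segments nuclei and cytoplasm from the stain channel, detects cytosolic
spots in the marker channel by intensity/area/contrast, and reduces fields
to per-cell and per-well summaries.  Also provides spot colocalization and
tandem-reporter (red/green) classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_multiotsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    nucleus_threshold: float | None = None      # None -> multi-Otsu auto
    cytoplasm_threshold: float | None = None
    min_nucleus_area: int = 20
    min_peak_distance: int = 7                  # watershed seed separation
    exclude_border_cells: bool = False
    stain_channel: int = 0
    marker_channel: int = 1


@dataclass
class SpotParams:
    min_area: int = 2
    intensity_threshold: float | None = None    # None -> robust auto
    contrast_threshold: float = 0.1
    auto_nsigma: float = 4.0                    # auto threshold: median + n*sigma
    smooth_sigma: float = 1.0                   # detection smoothing (0 = off)
    split_min_distance: int = 4                 # peak separation for de-merging
    integration_dilation: int = 3               # aperture radius around the blob
    annulus_width: int = 3                      # local-background ring width


CELL_COLUMNS = ["cell_id", "nucleus_row", "nucleus_col", "nucleus_area",
                "nucleus_intensity", "cytoplasm_area", "cytoplasm_intensity"]
SPOT_COLUMNS = ["spot_id", "cell_id", "row", "col", "area", "mean_intensity",
                "integrated_intensity", "contrast"]


def _auto_thresholds(channel: np.ndarray):
    """Background / cytoplasm / nucleus split via 3-class Otsu."""
    lo, hi = threshold_multiotsu(channel, classes=3)
    return float(lo), float(hi)


def segment_cells(image: np.ndarray, params: SegmentationParams | None = None):
    """Segment nuclei and cytoplasm from the stain channel.

    Nuclei are detected by thresholding the bright population, split by a
    distance-transform watershed, and grown into the cytoplasm-stain mask to
    assign each cell its cytoplasm territory.  Returns a ``(cells, masks)``
    pair: a DataFrame of per-cell records and a dict with ``nuclei`` /
    ``cells`` / ``cytoplasm`` label images (cytoplasm = cell minus nucleus).
    """
    params = params or SegmentationParams()
    stain = np.asarray(image[params.stain_channel], dtype=np.float64)

    empty = (pd.DataFrame(columns=CELL_COLUMNS), {
        "nuclei": np.zeros(stain.shape, dtype=np.int32),
        "cells": np.zeros(stain.shape, dtype=np.int32),
        "cytoplasm": np.zeros(stain.shape, dtype=np.int32),
    })
    if stain.max() <= stain.min():
        log.warning("flat stain channel; returning zero cells")
        return empty

    if params.nucleus_threshold is None or params.cytoplasm_threshold is None:
        try:
            lo, hi = _auto_thresholds(stain)
        except ValueError:
            log.warning("could not derive thresholds; returning zero cells")
            return empty
        cyto_thr = params.cytoplasm_threshold if params.cytoplasm_threshold is not None else lo
        nuc_thr = params.nucleus_threshold if params.nucleus_threshold is not None else hi
    else:
        cyto_thr, nuc_thr = params.cytoplasm_threshold, params.nucleus_threshold

    nuc_mask = stain > nuc_thr
    fg_mask = stain > cyto_thr
    nuc_mask = ndi.binary_fill_holes(nuc_mask)
    nuc_mask = ndi.binary_opening(nuc_mask, structure=disk(1))

    # split touching nuclei with a distance-transform watershed
    dist = ndi.distance_transform_edt(nuc_mask)
    from skimage.feature import peak_local_max
    peaks = peak_local_max(dist, min_distance=params.min_peak_distance,
                           labels=nuc_mask, exclude_border=False)
    seeds = np.zeros(stain.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    nuclei = watershed(-dist, seeds, mask=nuc_mask)

    # drop undersized nuclei
    for region in regionprops(nuclei):
        if region.area < params.min_nucleus_area:
            nuclei[nuclei == region.label] = 0
    nuclei, _, _ = _relabel(nuclei)

    if nuclei.max() == 0:
        log.warning("no nuclei above threshold; returning zero cells")
        return empty

    # grow cells from nuclear seeds, bounded by the cytoplasm-stain mask
    cells = watershed(-stain, nuclei, mask=fg_mask | (nuclei > 0))

    if params.exclude_border_cells:
        border_labels = np.unique(np.concatenate([
            cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]]))
        for lbl in border_labels:
            if lbl:
                cells[cells == lbl] = 0
                nuclei[nuclei == lbl] = 0

    cytoplasm = np.where(nuclei > 0, 0, cells)

    records = []
    for region in regionprops(nuclei, intensity_image=stain):
        lbl = region.label
        cyto_px = cytoplasm == lbl
        cy, cx = region.centroid_weighted
        records.append((lbl, float(cy), float(cx), int(region.area),
                        float(region.intensity_mean), int(cyto_px.sum()),
                        float(stain[cyto_px].mean()) if cyto_px.any() else 0.0))
    cells_df = pd.DataFrame(records, columns=CELL_COLUMNS)
    return cells_df, {"nuclei": nuclei.astype(np.int32),
                      "cells": cells.astype(np.int32),
                      "cytoplasm": cytoplasm.astype(np.int32)}


def _relabel(labels: np.ndarray):
    out, fwd, inv = None, {}, {}
    uniq = [l for l in np.unique(labels) if l != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(sorted(uniq), start=1):
        out[labels == old] = new
        fwd[old] = new
        inv[new] = old
    return out, fwd, inv


def detect_spots(image: np.ndarray, masks: dict,
                 params: SpotParams | None = None,
                 marker_channel: int = 1) -> pd.DataFrame:
    """Detect cytosolic spots in the marker channel.

    Candidate blobs are connected components above the intensity threshold,
    filtered by minimum area and by contrast against a local annulus
    background; blobs whose centroid falls outside every cytoplasm mask are
    discarded.  Contrast is (spot mean - background) / (spot mean +
    background); the integrated intensity is the background-corrected sum
    over a dilated aperture around the blob.
    """
    params = params or SpotParams()
    marker = np.asarray(image[marker_channel], dtype=np.float64)
    cyto = masks["cytoplasm"]

    detect_img = ndi.gaussian_filter(marker, params.smooth_sigma) \
        if params.smooth_sigma > 0 else marker
    if params.intensity_threshold is None:
        med = float(np.median(detect_img))
        sigma = 1.4826 * float(np.median(np.abs(detect_img - med)))
        thr = med + params.auto_nsigma * max(sigma, 1e-12)
    else:
        thr = params.intensity_threshold

    mask = detect_img > thr
    comp, _ = ndi.label(mask)
    if params.split_min_distance > 0 and comp.max() > 0:
        # de-merge touching spots: one watershed basin per local maximum
        from skimage.feature import peak_local_max
        peaks = peak_local_max(detect_img,
                               min_distance=params.split_min_distance,
                               labels=comp, exclude_border=False)
        seeds = np.zeros(detect_img.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            seeds[r, c] = i
        labels = watershed(-detect_img, seeds, mask=mask)
    else:
        labels = comp

    # first pass: candidate blobs surviving the area / location filters
    cands = []
    for region in regionprops(labels, intensity_image=detect_img):
        if region.area < params.min_area:
            continue
        cy, cx = region.centroid_weighted
        ri = min(max(int(round(cy)), 0), marker.shape[0] - 1)
        ci = min(max(int(round(cx)), 0), marker.shape[1] - 1)
        owner = int(cyto[ri, ci])
        if owner == 0:
            continue  # extracellular or nuclear: not a cytosolic spot
        cands.append((region.label, owner, float(cy), float(cx),
                      int(region.area)))
    if not cands:
        return pd.DataFrame(columns=SPOT_COLUMNS)

    # exclusive integration apertures: dilate each blob, assign contested
    # pixels to the nearest spot centroid so neighbours don't leak signal
    aperture_fp = disk(params.integration_dilation)
    apertures = []
    for lbl, *_ in cands:
        apertures.append(ndi.binary_dilation(labels == lbl,
                                             structure=aperture_fp))
    union = np.logical_or.reduce(apertures)
    centroids = np.array([[cy, cx] for _, _, cy, cx, _ in cands])
    tree = cKDTree(centroids)
    pix = np.argwhere(union)
    _, nearest = tree.query(pix, k=1)
    owner_map = np.full(marker.shape, -1, dtype=np.int32)
    owner_map[pix[:, 0], pix[:, 1]] = nearest

    annulus_fp = disk(params.integration_dilation + params.annulus_width)
    records = []
    spot_id = 0
    for i, (lbl, owner, cy, cx, area) in enumerate(cands):
        blob = labels == lbl
        aperture = apertures[i] & (owner_map == i)
        ring = ndi.binary_dilation(blob, structure=annulus_fp) & ~union
        background = float(np.median(marker[ring])) if ring.any() else 0.0

        spot_mean = float(marker[blob].mean())
        bg_c = max(background, 0.0)  # contrast stays in (-1, 1]
        denom = spot_mean + bg_c
        contrast = (spot_mean - bg_c) / denom if denom > 0 else 0.0
        if not contrast > params.contrast_threshold:
            continue
        integrated = float((marker[aperture] - background).sum())
        records.append((spot_id, owner, cy, cx, area, spot_mean,
                        max(integrated, 0.0), float(contrast)))
        spot_id += 1
    return pd.DataFrame(records, columns=SPOT_COLUMNS)


def summarize_well(cells: pd.DataFrame, spots: pd.DataFrame,
                   min_cells: int = 0) -> dict:
    """Reduce cell and spot records to a single well summary.

    Per-cell spot counts and summed background-corrected integrated
    intensities are averaged over all cells (cells with no spots count as
    zero).  Wells with no cells get NaN per-cell fields; wells below
    ``min_cells`` are flagged low-coverage.
    """
    n_cells = len(cells)
    if n_cells == 0:
        return {"n_cells": 0, "spots_per_cell": np.nan,
                "iss_per_cell": np.nan, "nucleus_intensity": np.nan,
                "nucleus_area": np.nan, "cytoplasm_intensity": np.nan,
                "cytoplasm_area": np.nan, "low_coverage": True}
    if len(spots) and not set(spots["cell_id"]).issubset(set(cells["cell_id"])):
        raise ValueError("spots reference unknown cell ids")
    spc = len(spots) / n_cells
    iss = float(spots["integrated_intensity"].sum()) / n_cells if len(spots) else 0.0
    return {
        "n_cells": n_cells,
        "spots_per_cell": float(spc),
        "iss_per_cell": iss,
        "nucleus_intensity": float(cells["nucleus_intensity"].mean()),
        "nucleus_area": float(cells["nucleus_area"].mean()),
        "cytoplasm_intensity": float(cells["cytoplasm_intensity"].mean()),
        "cytoplasm_area": float(cells["cytoplasm_area"].mean()),
        "low_coverage": n_cells < min_cells,
    }


def quantify_well(image: np.ndarray,
                  seg_params: SegmentationParams | None = None,
                  spot_params: SpotParams | None = None) -> dict:
    """segment + detect + summarize in one call."""
    cells, masks = segment_cells(image, seg_params)
    spots = detect_spots(image, masks, spot_params)
    return summarize_well(cells, spots)


def _centroids(spots) -> np.ndarray:
    if isinstance(spots, pd.DataFrame):
        return spots[["row", "col"]].to_numpy(dtype=float)
    return np.asarray(spots, dtype=float).reshape(-1, 2)


def colocalize_spots(spots_a, spots_b, radius: float = 3.0):
    """Mutual coalescence percentages of two spot lists.

    A spot of one list is colocalized if any centroid of the other list lies
    within ``radius`` pixels.  Returns ``(pct_a_with_b, pct_b_with_a)``;
    an empty list yields NaN for its direction.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    a, b = _centroids(spots_a), _centroids(spots_b)
    if len(a) == 0 and len(b) == 0:
        return (np.nan, np.nan)

    def pct(query, ref):
        if len(query) == 0:
            return np.nan
        if len(ref) == 0:
            return 0.0
        tree = cKDTree(ref)
        dists, _ = tree.query(query, k=1)
        return 100.0 * float(np.mean(dists <= radius))

    return (pct(a, b), pct(b, a))


def classify_tandem(spots_red, spots_green, radius: float = 3.0):
    """Tandem-reporter classification of red spots.

    Red spots with a green partner within ``radius`` are autophagosomes
    (RFP+GFP+); red-only spots are autolysosomes.  Returns
    ``(n_autophagosomes, n_autolysosomes, ratio)`` with the ratio NaN when
    there are no autolysosomes.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    red, green = _centroids(spots_red), _centroids(spots_green)
    if len(red) == 0:
        return (0, 0, np.nan)
    if len(green) == 0:
        return (0, len(red), 0.0)
    tree = cKDTree(green)
    dists, _ = tree.query(red, k=1)
    n_auto = int(np.sum(dists <= radius))
    n_lyso = len(red) - n_auto
    ratio = n_auto / n_lyso if n_lyso > 0 else np.nan
    return (n_auto, n_lyso, ratio)
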