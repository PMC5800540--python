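"""Investigator artifact remediation as an auditable, replayable edit ledger.

Manual correction of automatically segmented insulin ROIs (removal of
false-positive signal, re-inclusion of sub-threshold islets) is modeled as
an ordered list of add/remove region edits with reason tags. A saved ledger
replays to a bit-identical corrected mask, which is the machine-readable
analogue of keeping every corrected ROI on file for peer evaluation.

:func:`oracle_corrections` builds the ledger an idealized investigator
would produce, by comparing the automatic mask against the simulator's
ground truth; ``boundary_jitter_px`` emulates imprecise manual outlining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .core import BinaryMask, ConfigurationError, LedgerError, Micrograph
from .simulate import GroundTruth

__all__ = [
    "Edit",
    "CorrectionLedger",
    "CorrectionPolicy",
    "apply_ledger",
    "oracle_corrections",
    "export_overlay",
]

REASONS = ("noise", "weak_positive", "adipose", "lymph_node", "outside_tissue")
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _rle_encode(patch: np.ndarray) -> List[int]:
    """Run lengths of the flattened patch, alternating 0/1, starting with 0."""
    flat = np.asarray(patch, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:  # must start with a zero-run
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: Sequence[int], shape: Tuple[int, int]) -> np.ndarray:
    total = int(np.prod(shape))
    flat = np.zeros(total, dtype=bool)
    pos, value = 0, False
    for r in runs:
        if r:
            flat[pos : pos + r] = value
        pos += r
        value = not value
    if pos != total:
        raise LedgerError(f"run lengths cover {pos} pixels, patch has {total}")
    return flat.reshape(shape)


@dataclass
class Edit:
    """One remediation step: add or remove a region, with a reason tag.

    ``region`` is a JSON-friendly dict, either
    ``{"type": "polygon", "vertices": [[row, col], ...]}`` or
    ``{"type": "mask_patch", "origin": [r0, c0], "shape": [h, w],
    "rle": [...]}`` (run-length-encoded boolean patch).
    """

    action: str
    region: dict
    reason: str = "noise"
    note: str = ""

    def __post_init__(self) -> None:
        if self.action not in ("remove_region", "add_region"):
            raise ConfigurationError(f"unknown action {self.action!r}")
        if self.reason not in REASONS:
            raise ConfigurationError(f"unknown reason {self.reason!r}")


@dataclass
class CorrectionLedger:
    """Ordered, serializable list of edits bound to an image shape."""

    image_shape: Tuple[int, int]
    edits: List[Edit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edits)

    def to_json(self, path: Optional[Path] = None) -> str:
        doc = {
            "image_shape": list(self.image_shape),
            "edits": [
                {
                    "action": e.action,
                    "region": e.region,
                    "reason": e.reason,
                    "note": e.note,
                }
                for e in self.edits
            ],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CorrectionLedger":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith(".json")
        ):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(
            image_shape=tuple(doc["image_shape"]),
            edits=[Edit(**e) for e in doc["edits"]],
        )


def _rasterize(region: dict, shape: Tuple[int, int], edit_index: int) -> np.ndarray:
    try:
        kind = region["type"]
    except (TypeError, KeyError):
        raise LedgerError(f"edit {edit_index}: region has no 'type'")
    if kind == "polygon":
        verts = np.asarray(region.get("vertices", []), dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise LedgerError(
                f"edit {edit_index}: polygon needs >= 3 (row, col) vertices"
            )
        if (
            verts.min() < -0.5
            or verts[:, 0].max() > shape[0] - 0.5
            or verts[:, 1].max() > shape[1] - 0.5
        ):
            raise LedgerError(f"edit {edit_index}: polygon exceeds image bounds")
        out = np.zeros(shape, dtype=bool)
        rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
        out[rr, cc] = True
        return out
    if kind == "mask_patch":
        try:
            r0, c0 = (int(v) for v in region["origin"])
            h, w = (int(v) for v in region["shape"])
            patch = _rle_decode(region["rle"], (h, w))
        except (KeyError, ValueError, TypeError) as exc:
            raise LedgerError(f"edit {edit_index}: malformed mask_patch ({exc})")
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            raise LedgerError(f"edit {edit_index}: mask_patch exceeds image bounds")
        out = np.zeros(shape, dtype=bool)
        out[r0 : r0 + h, c0 : c0 + w] = patch
        return out
    raise LedgerError(f"edit {edit_index}: unknown region type {kind!r}")


def _patch_region_local(patch: np.ndarray, sl: Tuple[slice, slice]) -> dict:
    """mask_patch region from a component patch and its find_objects slice."""
    rows, cols = np.nonzero(patch)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    return {
        "type": "mask_patch",
        "origin": [sl[0].start + r0, sl[1].start + c0],
        "shape": [r1 - r0, c1 - c0],
        "rle": _rle_encode(patch[r0:r1, c0:c1]),
    }


def _patch_region(mask: np.ndarray) -> dict:
    """Bounding-box mask_patch region for a full-frame boolean mask."""
    rows, cols = np.nonzero(mask)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    return {
        "type": "mask_patch",
        "origin": [r0, c0],
        "shape": [r1 - r0, c1 - c0],
        "rle": _rle_encode(mask[r0:r1, c0:c1]),
    }


def apply_ledger(mask: BinaryMask, ledger: CorrectionLedger) -> BinaryMask:
    """Apply edits strictly in order; provenance becomes ``corrected``.

    ``remove_region`` is set difference, ``add_region`` is union, so a
    remove followed by an add of the same region leaves it present.
    """
    if tuple(ledger.image_shape) != tuple(mask.shape):
        raise LedgerError(
            f"ledger shape {ledger.image_shape} != mask shape {mask.shape}"
        )
    out = mask.mask.copy()
    for i, edit in enumerate(ledger.edits):
        region = _rasterize(edit.region, mask.shape, i)
        if edit.action == "remove_region":
            out &= ~region
        else:
            out |= region
    return BinaryMask(out, mask.pixel_size_mm, "corrected")


@dataclass
class CorrectionPolicy:
    """How the idealized investigator decides edits against ground truth."""

    min_overlap_fraction: float = 0.5
    recover_false_negatives: bool = True
    boundary_jitter_px: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_overlap_fraction <= 1.0):
            raise ConfigurationError("min_overlap_fraction must lie in [0, 1]")
        if self.boundary_jitter_px < 0:
            raise ConfigurationError("boundary_jitter_px must be >= 0")


def oracle_corrections(
    auto_mask: BinaryMask,
    truth: GroundTruth,
    policy: CorrectionPolicy = CorrectionPolicy(),
    seed: int = 0,
) -> CorrectionLedger:
    """Ground-truth-driven remediation ledger for an automatic insulin mask.

    Every 8-connected component of the automatic mask whose overlap fraction
    with the true beta mask is below ``policy.min_overlap_fraction`` becomes
    a ``remove_region`` edit; its reason is the confounder (speckle -> noise,
    adipose, lymph node) it overlaps most, defaulting to ``noise``. If
    ``recover_false_negatives``, every true islet component with no overlap
    against the surviving automatic mask becomes an ``add_region`` edit with
    the true outline dilated by a seeded random amount up to
    ``boundary_jitter_px`` (reason ``weak_positive``). Edits are ordered
    removals-first, each block sorted by component label.
    """
    if auto_mask.shape != truth.beta_mask.shape:
        raise ConfigurationError("mask and ground truth shapes differ")
    rng = np.random.default_rng(int(seed))
    beta = truth.beta_mask
    ledger = CorrectionLedger(image_shape=tuple(auto_mask.shape))

    labels, n = ndimage.label(auto_mask.mask, structure=_STRUCT8)
    kept = np.zeros_like(auto_mask.mask)
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        comp_px = int(comp.sum())
        overlap = int((comp & beta[sl]).sum()) / comp_px
        if overlap >= policy.min_overlap_fraction:
            kept[sl] |= comp
            continue
        reason = "noise"
        best = 0
        for name, conf in truth.confounder_masks.items():
            hit = int((comp & conf[sl]).sum())
            if hit > best:
                best = hit
                reason = "noise" if name == "speckle" else name
        ledger.edits.append(
            Edit(
                action="remove_region",
                region=_patch_region_local(comp, sl),
                reason=reason,
                note=f"auto component {lab}: overlap {overlap:.2f} with true signal",
            )
        )

    if policy.recover_false_negatives:
        tlabels, tn = ndimage.label(beta, structure=_STRUCT8)
        tslices = ndimage.find_objects(tlabels)
        for lab in range(1, tn + 1):
            sl = tslices[lab - 1]
            comp = tlabels[sl] == lab
            if (comp & kept[sl]).any():
                continue
            if policy.boundary_jitter_px > 0:
                j = int(rng.integers(0, policy.boundary_jitter_px + 1))
                if j > 0:
                    full = np.zeros(auto_mask.shape, dtype=bool)
                    full[sl] = comp
                    full = ndimage.binary_dilation(
                        full, iterations=j, structure=_STRUCT8
                    )
                    ledger.edits.append(
                        Edit(
                            action="add_region",
                            region=_patch_region(full),
                            reason="weak_positive",
                            note=f"true islet component {lab} missed by automatic mask",
                        )
                    )
                    continue
            ledger.edits.append(
                Edit(
                    action="add_region",
                    region=_patch_region_local(comp, sl),
                    reason="weak_positive",
                    note=f"true islet component {lab} missed by automatic mask",
                )
            )
    return ledger


# ---------------------------------------------------------------------------
# overlay rendering (deterministic, for peer-evaluation output files)

# 3x5 bitmap digits, enough to stamp particle labels into the overlay
_DIGITS = {
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def _stamp_text(rgb: np.ndarray, text: str, row: int, col: int) -> None:
    H, W = rgb.shape[:2]
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            col += 4
            continue
        for dr, line in enumerate(glyph):
            for dc, bit in enumerate(line):
                if bit == "1" and 0 <= row + dr < H and 0 <= col + dc < W:
                    rgb[row + dr, col + dc] = (255, 255, 255)
        col += 4


def export_overlay(
    micrograph: Micrograph,
    roi: BinaryMask,
    particle_table: pd.DataFrame,
    path: Optional[Path] = None,
) -> np.ndarray:
    """Composite RGB with ROI outlines and numbered kept particles.

    Nuclear channel renders blue, insulin green; the ROI outline is drawn in
    red and each kept particle's label is stamped in white at its centroid.
    Rendering is fully deterministic, so re-exports of identical inputs are
    byte-identical.
    """
    H, W = micrograph.shape
    rgb = np.zeros((H, W, 3), dtype=np.uint8)
    rgb[..., 1] = micrograph.insulin_channel
    rgb[..., 2] = micrograph.nuclear_channel
    if roi.mask.any():
        interior = ndimage.binary_erosion(roi.mask, structure=_STRUCT8)
        outline = roi.mask & ~interior
        rgb[outline] = (255, 0, 0)
    for _, p in particle_table.iterrows():
        if not p["kept"]:
            continue
        _stamp_text(
            rgb, str(int(p["label"])), int(p["centroid_row"]), int(p["centroid_col"])
        )
    if path is not None:
        iio.imwrite(Path(path), rgb)
    return rgb
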