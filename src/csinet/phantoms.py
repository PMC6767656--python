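"""Procedural synthetic breast phantoms with tissue-region priors.

Each phantom is a 2D complex relative-permittivity map built from a tissue
label map with five classes: exterior matching medium, a closed skin ring,
a fat region, one contiguous fibroglandular region, and one or two tumors
grown inside the fibroglandular tissue.  Three base outlines emulate breast
density classes: Model I, a heterogeneously dense breast of 10 x 9.5 cm;
Model II, a fatty breast of 11.2 x 9.6 cm; Model III, a very dense breast
of 10 x 5 cm.  Density class controls the fibroglandular area fraction
(II < I < III).

A surrogate three-region prior ("numerical background") is derived from
each phantom by deleting the tumor class, optionally jittering region
boundaries with a smooth random displacement field and perturbing the
per-region permittivity values — emulating an imperfect ultrasound-derived
tissue segmentation without simulating ultrasound itself.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .constants import (
    DEFAULT_TISSUE_TABLE,
    LABEL_EXTERIOR,
    LABEL_FAT,
    LABEL_FIBROGLANDULAR,
    LABEL_SKIN,
    LABEL_TUMOR,
)

MODEL_IDS = ("I", "II", "III")

#: breast outline (width, height) in cm per base model
MODEL_DIMENSIONS_CM = {
    "I": (10.0, 9.5),
    "II": (11.2, 9.6),
    "III": (10.0, 5.0),
}

#: target fibroglandular area fraction of the breast interior per density
#: class (fatty smallest, very dense largest)
MODEL_FIBRO_FRACTION = {
    "I": 0.35,
    "II": 0.15,
    "III": 0.65,
}

#: default tumor maximum-diameter range, cm
TUMOR_DIAMETER_RANGE_CM = (1.1, 1.5)

#: physical skin thickness target, cm (realised as 1-3 whole pixels)
SKIN_THICKNESS_CM = 0.2


@dataclasses.dataclass
class TissueLabelMap:
    """Integer tissue-label grid with physical pixel size."""

    labels: np.ndarray  # (M, N) int array with codes 0..4
    pixel_size: float  # cm per pixel
    model_id: str

    @property
    def shape(self):
        return self.labels.shape

    def interior_mask(self):
        """Pixels inside the skin (fat, fibroglandular or tumor)."""
        return np.isin(self.labels, (LABEL_FAT, LABEL_FIBROGLANDULAR, LABEL_TUMOR))

    def breast_mask(self):
        """All tissue pixels including the skin ring."""
        return self.labels != LABEL_EXTERIOR


@dataclasses.dataclass
class Phantom:
    """Complex permittivity map plus its generating label map."""

    eps_real: np.ndarray
    eps_imag: np.ndarray  # loss term, >= 0 (eps = eps' - j eps'')
    labels: TissueLabelMap
    tumor_mask: np.ndarray
    n_tumors: int
    rng_seed: int | None = None
    tissue_table: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE)
    )

    @property
    def eps(self) -> np.ndarray:
        """Complex relative permittivity eps' - j*eps''."""
        return self.eps_real - 1j * self.eps_imag

    @property
    def pixel_size(self) -> float:
        return self.labels.pixel_size


@dataclasses.dataclass
class PriorBackground:
    """Tumor-free piecewise-constant numerical background eps_n."""

    eps_n_real: np.ndarray
    eps_n_imag: np.ndarray
    region_labels: TissueLabelMap
    boundary_jitter: float  # pixels

    @property
    def eps_n(self) -> np.ndarray:
        return self.eps_n_real - 1j * self.eps_n_imag


def _ellipse_mask(shape, pixel_size, width_cm, height_cm):
    m, n = shape
    # pixel centres in cm relative to the grid centre
    y = (np.arange(m) + 0.5) * pixel_size - m * pixel_size / 2.0
    x = (np.arange(n) + 0.5) * pixel_size - n * pixel_size / 2.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    a = width_cm / 2.0
    b = height_cm / 2.0
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


def make_base_model(model_id, grid_shape, pixel_size, rng) -> TissueLabelMap:
    """Build the tissue label map for one of the three base breast models.

    Parameters
    ----------
    model_id : {"I", "II", "III"}
        Density class: I heterogeneously dense, II fatty, III very dense.
    grid_shape : (int, int)
        Output grid rows/cols.
    pixel_size : float
        Pixel edge length in cm.
    rng : numpy.random.Generator
        Drives the fibroglandular blob shape; geometry is otherwise fixed.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(
            f"unknown model_id {model_id!r}; valid ids are {', '.join(MODEL_IDS)}"
        )
    rng = np.random.default_rng(rng)
    w_cm, h_cm = MODEL_DIMENSIONS_CM[model_id]
    m, n = grid_shape
    if w_cm > n * pixel_size or h_cm > m * pixel_size:
        raise ValueError(
            f"grid {grid_shape} at {pixel_size} cm/px cannot hold the "
            f"{w_cm} x {h_cm} cm outline of model {model_id}"
        )

    breast = _ellipse_mask(grid_shape, pixel_size, w_cm, h_cm)
    skin_px = int(np.clip(round(SKIN_THICKNESS_CM / pixel_size), 1, 3))
    interior = ndimage.binary_erosion(breast, iterations=skin_px)

    labels = np.full(grid_shape, LABEL_EXTERIOR, dtype=np.int8)
    labels[breast] = LABEL_SKIN
    labels[interior] = LABEL_FAT

    # fibroglandular region: thresholded smooth Gaussian random field inside
    # the interior (kept one pixel off the skin), largest connected component
    zone = ndimage.binary_erosion(interior, iterations=1)
    field = ndimage.gaussian_filter(
        rng.standard_normal(grid_shape), sigma=0.8 / pixel_size
    )
    # bias the field toward the breast centre so the blob is central and
    # usually singly connected
    dist = ndimage.distance_transform_edt(interior)
    field = field + 0.15 * dist / max(dist.max(), 1.0) * field.std() * 10

    n_interior = int(interior.sum())
    n_target = int(MODEL_FIBRO_FRACTION[model_id] * n_interior)
    vals = field[zone]
    if n_target >= vals.size:
        fibro = zone.copy()
    else:
        thr = np.partition(vals, vals.size - n_target)[vals.size - n_target]
        fibro = zone & (field >= thr)
    lab, _ = ndimage.label(fibro)
    if lab.max() > 0:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, lab.max() + 1))
        fibro = lab == (1 + int(np.argmax(sizes)))
    labels[fibro] = LABEL_FIBROGLANDULAR
    return TissueLabelMap(labels=labels, pixel_size=pixel_size, model_id=model_id)


def grow_tumor(labels: TissueLabelMap, max_diameter_cm, rng, forbidden=None):
    """Grow one random 4-connected tumor inside the fibroglandular region.

    Starting from a uniformly chosen fibroglandular pixel, contiguous
    pixels are accreted in random order; a candidate is rejected
    permanently if adding it would make the maximum pairwise pixel-centre
    distance reach ``max_diameter_cm``.  Growth stops when no candidate
    remains.

    Parameters
    ----------
    forbidden : bool array, optional
        Pixels the tumor may not occupy or touch (e.g. an earlier tumor).

    Returns
    -------
    bool array of the tumor mask.
    """
    rng = np.random.default_rng(rng)
    px = labels.pixel_size
    fibro = labels.labels == LABEL_FIBROGLANDULAR
    n_needed = (max_diameter_cm / px) ** 2
    if fibro.sum() < max(1, n_needed):
        raise ValueError(
            "fibroglandular region too small to seed a tumor of "
            f"max diameter {max_diameter_cm} cm"
        )
    eligible = fibro if forbidden is None else fibro & ~forbidden
    if not eligible.any():
        raise ValueError("no eligible seed pixel for tumor growth")
    idx = np.flatnonzero(eligible)
    seed_flat = idx[rng.integers(idx.size)]
    m, n = labels.shape
    seed = np.array(divmod(seed_flat, n))

    rmax_px = max_diameter_cm / px
    pts = [seed]
    in_mask = np.zeros((m, n), dtype=bool)
    in_mask[seed[0], seed[1]] = True
    rejected = np.zeros((m, n), dtype=bool)
    frontier = []

    def push_neighbors(p):
        i, j = p
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < m and 0 <= b < n and eligible[a, b] and not in_mask[a, b] and not rejected[a, b]:
                frontier.append((a, b))

    push_neighbors(seed)
    arr = np.array(pts)
    while frontier:
        k = rng.integers(len(frontier))
        cand = frontier.pop(k)
        if in_mask[cand] or rejected[cand]:
            continue
        d = np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1]).max()
        if d < rmax_px:
            in_mask[cand] = True
            arr = np.vstack([arr, cand])
            push_neighbors(cand)
        else:
            rejected[cand] = True
    return in_mask


def assign_permittivity(labels: TissueLabelMap, tissue_table=None,
                        texture_level=0.05, rng=None, tumor_mask=None,
                        rng_seed=None) -> Phantom:
    """Map tissue labels to complex permittivity with bounded texture.

    Each tissue pixel takes its table value scaled by (1 + u) with u
    uniform in [-texture_level, +texture_level]; the exterior matching
    medium stays exactly at its table value.
    """
    rng = np.random.default_rng(rng)
    table = dict(DEFAULT_TISSUE_TABLE if tissue_table is None else tissue_table)
    lab = labels.labels.copy()
    if tumor_mask is not None:
        lab[tumor_mask] = LABEL_TUMOR
    present = np.unique(lab)
    missing = [int(c) for c in present if int(c) not in table]
    if missing:
        raise ValueError(f"tissue_table missing entries for labels {missing}")

    eps = np.zeros(lab.shape, dtype=complex)
    for code in present:
        eps[lab == code] = table[int(code)]
    if texture_level > 0:
        u = rng.uniform(-texture_level, texture_level, size=lab.shape)
        tissue = lab != LABEL_EXTERIOR
        eps[tissue] *= 1.0 + u[tissue]

    tmask = lab == LABEL_TUMOR
    new_labels = TissueLabelMap(lab, labels.pixel_size, labels.model_id)
    return Phantom(
        eps_real=eps.real.copy(),
        eps_imag=(-eps.imag).copy(),
        labels=new_labels,
        tumor_mask=tmask,
        n_tumors=int(ndimage.label(tmask)[1]),
        rng_seed=rng_seed,
        tissue_table=table,
    )


def make_prior(phantom: Phantom, boundary_jitter_px=0.0, value_error_frac=0.0,
               rng=None) -> PriorBackground:
    """Surrogate three-region prior: tumor-free, optionally imperfect.

    Tumor pixels are relabelled fibroglandular.  Region boundaries are
    displaced by a smooth random field whose maximum displacement is
    ``boundary_jitter_px`` pixels, and per-region permittivities are the
    tissue-table values scaled by (1 + e) with e uniform in
    [-value_error_frac, +value_error_frac] (the known exterior medium is
    never perturbed).  With jitter 0 and error 0 the prior equals the
    exact tumor-free piecewise-constant background.
    """
    rng = np.random.default_rng(rng)
    lab = phantom.labels.labels.copy()
    lab[lab == LABEL_TUMOR] = LABEL_FIBROGLANDULAR

    if boundary_jitter_px > 0:
        m, n = lab.shape
        dy = ndimage.gaussian_filter(rng.standard_normal((m, n)), sigma=4.0)
        dx = ndimage.gaussian_filter(rng.standard_normal((m, n)), sigma=4.0)
        scale = max(np.abs(dy).max(), np.abs(dx).max(), 1e-12)
        dy = dy / scale * boundary_jitter_px
        dx = dx / scale * boundary_jitter_px
        ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
        lab = ndimage.map_coordinates(lab, [ii + dy, jj + dx], order=0, mode="nearest")

    eps = np.zeros(lab.shape, dtype=complex)
    for code in np.unique(lab):
        v = phantom.tissue_table[int(code)]
        if value_error_frac > 0 and code != LABEL_EXTERIOR:
            v = v * (1.0 + rng.uniform(-value_error_frac, value_error_frac))
        eps[lab == code] = v

    region_labels = TissueLabelMap(lab, phantom.pixel_size, phantom.labels.model_id)
    return PriorBackground(
        eps_n_real=eps.real.copy(),
        eps_n_imag=(-eps.imag).copy(),
        region_labels=region_labels,
        boundary_jitter=float(boundary_jitter_px),
    )


def make_phantom(model_id, grid_shape, pixel_size, rng, n_tumors=1,
                 tissue_table=None, texture_level=0.05,
                 tumor_diameter_range=TUMOR_DIAMETER_RANGE_CM,
                 rng_seed=None) -> Phantom:
    """Convenience: base model + grown tumor(s) + permittivity assignment."""
    rng = np.random.default_rng(rng)
    labels = make_base_model(model_id, grid_shape, pixel_size, rng)
    tumor = np.zeros(grid_shape, dtype=bool)
    for k in range(n_tumors):
        dmax = rng.uniform(*tumor_diameter_range)
        if k == 0:
            tumor |= grow_tumor(labels, dmax, rng)
        else:
            # the second tumor may not touch the first (8-connectivity)
            halo = ndimage.binary_dilation(tumor, structure=np.ones((3, 3)))
            for attempt in range(100):
                cand = grow_tumor(labels, dmax, rng, forbidden=halo)
                if not (cand & halo).any():
                    tumor |= cand
                    break
            else:
                raise RuntimeError("could not place a non-touching second tumor")
    return assign_permittivity(labels, tissue_table, texture_level, rng,
                               tumor_mask=tumor, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# dataset generation and storage


@dataclasses.dataclass
class DatasetManifest:
    """Index of a generated phantom dataset with 4-fold assignment."""

    entries: list  # dicts: path, model_id, n_tumors, fold, seed
    master_seed: int

    def to_json(self, path):
        Path(path).write_text(
            json.dumps(
                {"master_seed": self.master_seed, "entries": self.entries}, indent=1
            )
        )

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(entries=d["entries"], master_seed=d["master_seed"])


def save_phantom(path, phantom: Phantom, prior: PriorBackground | None = None):
    with h5py.File(path, "w") as f:
        f["eps_real"] = phantom.eps_real
        f["eps_imag"] = phantom.eps_imag
        f["labels"] = phantom.labels.labels
        f["tumor_mask"] = phantom.tumor_mask
        f.attrs["pixel_size_cm"] = phantom.pixel_size
        f.attrs["model_id"] = phantom.labels.model_id
        f.attrs["n_tumors"] = phantom.n_tumors
        f.attrs["seed"] = -1 if phantom.rng_seed is None else phantom.rng_seed
        f.attrs["tissue_table"] = json.dumps(
            {str(k): [v.real, -v.imag] for k, v in phantom.tissue_table.items()}
        )
        if prior is not None:
            f["prior/eps_n_real"] = prior.eps_n_real
            f["prior/eps_n_imag"] = prior.eps_n_imag
            f["prior/region_labels"] = prior.region_labels.labels
            f.attrs["boundary_jitter_px"] = prior.boundary_jitter


def load_phantom(path):
    with h5py.File(path, "r") as f:
        table = {
            int(k): v[0] - 1j * v[1]
            for k, v in json.loads(f.attrs["tissue_table"]).items()
        }
        labels = TissueLabelMap(
            f["labels"][...], float(f.attrs["pixel_size_cm"]), str(f.attrs["model_id"])
        )
        seed = int(f.attrs["seed"])
        phantom = Phantom(
            eps_real=f["eps_real"][...],
            eps_imag=f["eps_imag"][...],
            labels=labels,
            tumor_mask=f["tumor_mask"][...].astype(bool),
            n_tumors=int(f.attrs["n_tumors"]),
            rng_seed=None if seed < 0 else seed,
            tissue_table=table,
        )
        prior = None
        if "prior" in f:
            prior = PriorBackground(
                eps_n_real=f["prior/eps_n_real"][...],
                eps_n_imag=f["prior/eps_n_imag"][...],
                region_labels=TissueLabelMap(
                    f["prior/region_labels"][...], labels.pixel_size, labels.model_id
                ),
                boundary_jitter=float(f.attrs.get("boundary_jitter_px", 0.0)),
            )
    return phantom, prior


def generate_dataset(per_model_single, per_model_double, master_seed, out_dir,
                     grid_shape=(128, 128), pixel_size=0.1, texture_level=0.05,
                     boundary_jitter_px=2.0, value_error_frac=0.05,
                     tissue_table=None, n_folds=4) -> DatasetManifest:
    """Generate and store phantoms plus priors for all three base models.

    Per model, ``per_model_single`` single-tumor and ``per_model_double``
    two-tumor phantoms are written.  Fold assignment is balanced per
    (model, tumor count) group and is a pure function of master_seed and
    the entry index.  Fully reproducible from ``master_seed``.
    """
    if per_model_single < 0 or per_model_double < 0:
        raise ValueError("phantom counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    idx = 0
    for model_id in MODEL_IDS:
        for n_tumors, count in ((1, per_model_single), (2, per_model_double)):
            group = []
            for k in range(count):
                ss = np.random.SeedSequence([master_seed, idx])
                seed = int(ss.generate_state(1)[0] % (2**31))
                rng = np.random.default_rng(ss)
                phantom = make_phantom(
                    model_id, grid_shape, pixel_size, rng, n_tumors=n_tumors,
                    tissue_table=tissue_table, texture_level=texture_level,
                    rng_seed=seed,
                )
                prior = make_prior(phantom, boundary_jitter_px, value_error_frac, rng)
                name = f"phantom_{idx:05d}_{model_id}_{n_tumors}t.h5"
                save_phantom(out_dir / name, phantom, prior)
                group.append(
                    {"path": name, "model_id": model_id, "n_tumors": n_tumors,
                     "seed": seed, "index": idx}
                )
                idx += 1
            # balanced fold assignment: seeded shuffle then round-robin
            group_key = 1000 + MODEL_IDS.index(model_id) * 10 + n_tumors
            perm = np.random.default_rng(
                np.random.SeedSequence([master_seed, group_key])
            ).permutation(len(group))
            for pos, g in enumerate(np.array(group, dtype=object)[perm]):
                g["fold"] = pos % n_folds
            entries.extend(group)
    entries.sort(key=lambda e: e["index"])
    manifest = DatasetManifest(entries=entries, master_seed=master_seed)
    manifest.to_json(out_dir / "manifest.json")
    return manifest
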