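"""End-to-end orchestration: generate -> forward -> invert -> train -> evaluate.

A single master seed determines every stochastic choice (phantom shapes,
tumor growth, measurement noise, training shuffles, weight init); each
stage derives its own seed stream from (master seed, stage name, item
index), so stages are decoupled and independently reproducible.

Two problem scales are bundled: the ``full`` preset mirrors the study
conditions (128x128 grid at 0.1 cm, 200+200 phantoms per model, 250 CSI
iterations, 75 epochs, four folds), and the ``desk`` preset is a
down-scaled configuration (64x64 grid at 0.2 cm, 10+10 phantoms per
model, 30 CSI iterations, 40 epochs, one fold) sized so the whole
pipeline runs on a laptop CPU in minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import phantoms as ph
from .csi import ContrastSourceInversion
from .evaluate import (ReconstructionBundle, robustness_suite,
                       run_cross_validation, render_report)
from .forward import (AcquisitionGeometry, ScatterDataset, add_noise,
                      build_mesh, forward_scatter)
from .unet import TrainConfig, save_unet_results


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PhysicsBlock:
    frequency: float = 1.0e9
    n_tx: int = 24
    n_rx: int = 24
    background_eps_real: float = 23.0
    background_eps_imag: float = 1.0
    noise_level: float = 0.05
    inv_mesh_frac: float = 0.1        # inversion mesh: lambda_min / 10
    fwd_mesh_frac: float = 1.0 / 15.0  # forward mesh ~1.5x finer

    @property
    def background_eps(self):
        return self.background_eps_real - 1j * self.background_eps_imag


@dataclasses.dataclass
class DatasetBlock:
    grid: int = 128
    pixel_size: float = 0.1
    per_model_single: int = 200
    per_model_double: int = 200
    texture_level: float = 0.05
    boundary_jitter_px: float = 2.0
    value_error_frac: float = 0.05
    tumor_diameter_min: float = 1.1
    tumor_diameter_max: float = 1.5


@dataclasses.dataclass
class CSIBlock:
    n_iters: int = 250
    snapshot_iters: tuple = (20, 150, 250)


@dataclasses.dataclass
class TrainBlock:
    architecture: int = 1
    epochs: int = 75
    batch_size: int = 10
    learning_rate: float = 1e-3
    base_filters: int = 32
    depth: int = 4


@dataclasses.dataclass
class EvalBlock:
    settings: tuple = ("A", "B", "C", "D")
    folds: tuple = (0, 1, 2, 3)
    robustness: bool = True


@dataclasses.dataclass
class RunConfig:
    master_seed: int = 0
    physics: PhysicsBlock = dataclasses.field(default_factory=PhysicsBlock)
    dataset: DatasetBlock = dataclasses.field(default_factory=DatasetBlock)
    csi: CSIBlock = dataclasses.field(default_factory=CSIBlock)
    training: TrainBlock = dataclasses.field(default_factory=TrainBlock)
    evaluation: EvalBlock = dataclasses.field(default_factory=EvalBlock)

    @classmethod
    def desk(cls, master_seed=0):
        """Laptop-scale preset used by the package's own validation runs."""
        return cls(
            master_seed=master_seed,
            dataset=DatasetBlock(grid=64, pixel_size=0.2, per_model_single=10,
                                 per_model_double=10),
            csi=CSIBlock(n_iters=30, snapshot_iters=(10, 20, 30)),
            training=TrainBlock(architecture=1, epochs=40, learning_rate=3e-3,
                                base_filters=8, depth=3),
            evaluation=EvalBlock(settings=("A",), folds=(0,)),
        )

    @classmethod
    def full(cls, master_seed=0):
        """Study-scale preset (hours of CPU time)."""
        return cls(master_seed=master_seed)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            master_seed=d.get("master_seed", 0),
            physics=PhysicsBlock(**d.get("physics", {})),
            dataset=DatasetBlock(**d.get("dataset", {})),
            csi=CSIBlock(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in d.get("csi", {}).items()}),
            training=TrainBlock(**d.get("training", {})),
            evaluation=EvalBlock(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d.get("evaluation", {}).items()}),
        )

    def geometry(self) -> AcquisitionGeometry:
        p, dset = self.physics, self.dataset
        return AcquisitionGeometry.circular(
            domain_half_width=dset.grid * dset.pixel_size / 2.0,
            frequency=p.frequency, n_tx=p.n_tx, n_rx=p.n_rx,
            background_eps=p.background_eps,
        )


def stage_seed(master_seed, stage, index=0):
    """Deterministic per-(stage, item) seed stream."""
    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    return np.random.SeedSequence([int(master_seed), tag, int(index)])


def _config_hash(obj):
    return hashlib.md5(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# in-memory study runner


def simulate_bundle(config: RunConfig, progress=False) -> ReconstructionBundle:
    """Generate phantoms, simulate data and invert — all in memory.

    Returns a :class:`ReconstructionBundle` with CSI reconstructions at
    the final iteration and at every configured snapshot iteration.
    """
    geo = config.geometry()
    dset, phys, csicfg = config.dataset, config.physics, config.csi
    eps_max = 1.2 * max(v.real for v in ph.DEFAULT_TISSUE_TABLE.values())
    fwd_mesh = build_mesh(geo, eps_max, phys.fwd_mesh_frac)
    inv_mesh = build_mesh(geo, eps_max, phys.inv_mesh_frac)
    grid_shape = (dset.grid, dset.grid)

    specs = []
    for model_id in ph.MODEL_IDS:
        for n_tumors, count in ((1, dset.per_model_single),
                                (2, dset.per_model_double)):
            specs += [(model_id, n_tumors)] * count

    n = len(specs)
    csi_r = np.zeros((n,) + grid_shape)
    csi_i = np.zeros((n,) + grid_shape)
    true_r = np.zeros((n,) + grid_shape)
    true_i = np.zeros((n,) + grid_shape)
    tmasks = np.zeros((n,) + grid_shape, dtype=bool)
    emasks = np.zeros((n,) + grid_shape, dtype=bool)
    model_ids = np.empty(n, dtype=object)
    snap_r = {it: np.zeros((n,) + grid_shape) for it in csicfg.snapshot_iters}
    snap_i = {it: np.zeros((n,) + grid_shape) for it in csicfg.snapshot_iters}

    for i, (model_id, n_tumors) in enumerate(specs):
        t0 = time.time()
        rng = np.random.default_rng(stage_seed(config.master_seed, "generate", i))
        phantom = ph.make_phantom(
            model_id, grid_shape, dset.pixel_size, rng, n_tumors=n_tumors,
            texture_level=dset.texture_level,
            tumor_diameter_range=(dset.tumor_diameter_min, dset.tumor_diameter_max),
        )
        prior = ph.make_prior(phantom, dset.boundary_jitter_px,
                              dset.value_error_frac, rng)
        ds = forward_scatter(phantom, geo, mesh=fwd_mesh, background=prior)
        noise_rng = np.random.default_rng(stage_seed(config.master_seed, "noise", i))
        ds = add_noise(ds, phys.noise_level, noise_rng)
        res = ContrastSourceInversion(ds, prior, mesh=inv_mesh).fit(
            n_iters=csicfg.n_iters, snapshot_iters=csicfg.snapshot_iters
        )
        eps_img = res.eps_image()
        csi_r[i], csi_i[i] = eps_img.real, -eps_img.imag
        for it in csicfg.snapshot_iters:
            s = res.eps_image(iteration=it)
            snap_r[it][i], snap_i[it][i] = s.real, -s.imag
        true_r[i], true_i[i] = phantom.eps_real, phantom.eps_imag
        tmasks[i] = phantom.tumor_mask
        emasks[i] = phantom.labels.interior_mask()
        model_ids[i] = model_id
        if progress:
            print(f"  phantom {i + 1}/{n} ({model_id}, {n_tumors} tumor) "
                  f"{time.time() - t0:.1f}s", flush=True)

    folds = fold_assignment(specs, config.master_seed)
    return ReconstructionBundle(
        csi_real=csi_r, csi_imag=csi_i, true_real=true_r, true_imag=true_i,
        tumor_masks=tmasks, eval_masks=emasks,
        model_ids=np.asarray(model_ids, dtype=str), folds=folds,
        snapshots={it: (snap_r[it], snap_i[it]) for it in csicfg.snapshot_iters},
    )


def fold_assignment(specs, master_seed, n_folds=4):
    """Balanced 4-fold assignment per (model, tumor-count) group."""
    folds = np.zeros(len(specs), dtype=int)
    keys = sorted(set(specs))
    for key in keys:
        idx = [i for i, s in enumerate(specs) if s == key]
        group_key = 1000 + ph.MODEL_IDS.index(key[0]) * 10 + key[1]
        perm = np.random.default_rng(
            np.random.SeedSequence([master_seed, group_key])
        ).permutation(len(idx))
        for pos, j in enumerate(perm):
            folds[idx[j]] = pos % n_folds
    return folds


def run_study(config: RunConfig, progress=False):
    """Simulate, cross-validate and stress-test; returns all artifacts.

    Returns (bundle, report, unet_results, robustness_report).
    """
    bundle = simulate_bundle(config, progress=progress)
    tcfg = TrainConfig(
        architecture=config.training.architecture,
        batch_size=config.training.batch_size,
        epochs=config.training.epochs,
        learning_rate=config.training.learning_rate,
        base_filters=config.training.base_filters,
        depth=config.training.depth,
        seed=int(stage_seed(config.master_seed, "train").generate_state(1)[0] % 2**31),
    )
    report, results = run_cross_validation(
        bundle, settings=config.evaluation.settings,
        architecture=config.training.architecture, train_config=tcfg,
        folds=config.evaluation.folds,
    )
    rob = None
    if config.evaluation.robustness and results is not None:
        test_sel = np.isin(bundle.folds, config.evaluation.folds)
        rob = robustness_suite(results, bundle.subset(test_sel))
    return bundle, report, results, rob


# ---------------------------------------------------------------------------
# cached on-disk pipeline


STAGES = ("generate", "forward", "invert", "evaluate")


def run_pipeline(config: RunConfig, out_dir, progress=True, force=False):
    """Cached on-disk pipeline; reruns only stages whose config changed.

    Each stage writes its outputs plus a hash of the configuration slice
    it depends on; a rerun with an unchanged config skips the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = []

    def stage_guard(name, cfg_slice):
        h = _config_hash(cfg_slice)
        marker = out_dir / f".{name}.hash"
        if not force and marker.exists() and marker.read_text() == h:
            log.append({"stage": name, "skipped": True})
            if progress:
                print(f"[{name}] cached, skipping", flush=True)
            return None
        return marker, h

    cfgd = dataclasses.asdict(config)
    t_all = time.time()

    # Stage 1+2+3 share the simulation (in-memory, then persisted)
    sim_slice = {k: cfgd[k] for k in ("master_seed", "physics", "dataset", "csi")}
    bundle_path = out_dir / "bundle.npz"
    guard = stage_guard("simulate", sim_slice)
    if guard is not None:
        t0 = time.time()
        if progress:
            print("[simulate] generating phantoms, forward data and CSI "
                  "reconstructions", flush=True)
        bundle = simulate_bundle(config, progress=progress)
        save_bundle(bundle, bundle_path)
        guard[0].write_text(guard[1])
        log.append({"stage": "simulate", "seconds": time.time() - t0})
    else:
        bundle = load_bundle(bundle_path)

    guard = stage_guard("evaluate", cfgd)
    if guard is not None:
        t0 = time.time()
        if progress:
            print("[evaluate] training and evaluating networks", flush=True)
        _, report, results, rob = run_study_from_bundle(config, bundle)
        render_report(report, out_dir / "eval", stem="report")
        if results is not None:
            save_unet_results(results, out_dir / "eval" / "unet_last")
        if rob is not None:
            render_report(rob, out_dir / "eval", stem="robustness", plot=False)
        guard[0].write_text(guard[1])
        log.append({"stage": "evaluate", "seconds": time.time() - t0})

    prov = {
        "config": cfgd,
        "config_hash": _config_hash(cfgd),
        "stages": log,
        "total_seconds": time.time() - t_all,
    }
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return out_dir


def run_study_from_bundle(config: RunConfig, bundle):
    tcfg = TrainConfig(
        architecture=config.training.architecture,
        batch_size=config.training.batch_size,
        epochs=config.training.epochs,
        learning_rate=config.training.learning_rate,
        base_filters=config.training.base_filters,
        depth=config.training.depth,
        seed=int(stage_seed(config.master_seed, "train").generate_state(1)[0] % 2**31),
    )
    report, results = run_cross_validation(
        bundle, settings=config.evaluation.settings,
        architecture=config.training.architecture, train_config=tcfg,
        folds=config.evaluation.folds,
    )
    rob = None
    if config.evaluation.robustness and results is not None:
        test_sel = np.isin(bundle.folds, config.evaluation.folds)
        rob = robustness_suite(results, bundle.subset(test_sel))
    return bundle, report, results, rob


def save_bundle(bundle: ReconstructionBundle, path):
    arrays = {
        "csi_real": bundle.csi_real, "csi_imag": bundle.csi_imag,
        "true_real": bundle.true_real, "true_imag": bundle.true_imag,
        "tumor_masks": bundle.tumor_masks, "eval_masks": bundle.eval_masks,
        "model_ids": bundle.model_ids.astype("U4"), "folds": bundle.folds,
    }
    for it, (r, i) in bundle.snapshots.items():
        arrays[f"snap_real_{it}"] = r
        arrays[f"snap_imag_{it}"] = i
    np.savez_compressed(path, **arrays)


def load_bundle(path) -> ReconstructionBundle:
    d = np.load(path, allow_pickle=False)
    snaps = {}
    for key in d.files:
        if key.startswith("snap_real_"):
            it = int(key.rsplit("_", 1)[1])
            snaps[it] = (d[f"snap_real_{it}"], d[f"snap_imag_{it}"])
    return ReconstructionBundle(
        csi_real=d["csi_real"], csi_imag=d["csi_imag"],
        true_real=d["true_real"], true_imag=d["true_imag"],
        tumor_masks=d["tumor_masks"].astype(bool),
        eval_masks=d["eval_masks"].astype(bool),
        model_ids=d["model_ids"].astype(str), folds=d["folds"],
        snapshots=snaps,
    )


# ---------------------------------------------------------------------------
# canned test assets


def fixture_suite(out_dir):
    """Write the tiny deterministic assets used for hand-checkable tests.

    * ``toy_csi.json`` — a 3-node dense operator problem with a known
      consistent (chi, w) pair (F_CSI = 0 at the solution);
    * ``mie_case.json`` — cylinder scattering case with series-oracle
      receiver fields;
    * ``phantom_32x32.h5`` — a small single-tumor phantom;
    * ``roc_toy.json`` — the 6-pixel ROC example with its brute-force AUC.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(1234)

    # 3-node toy: random small complex operators, consistent data
    n_d, n_rx, n_tx = 3, 2, 2
    L = rng.standard_normal((4, n_d)) + 1j * rng.standard_normal((4, n_d))
    Ms = rng.standard_normal((n_rx, 4)) + 1j * rng.standard_normal((n_rx, 4))
    Md = rng.standard_normal((n_d, 4)) + 1j * rng.standard_normal((n_d, 4))
    einc = rng.standard_normal((n_d, n_tx)) + 1j * rng.standard_normal((n_d, n_tx))
    chi = 0.3 * (rng.standard_normal(n_d) + 1j * rng.standard_normal(n_d))
    # consistent sources: solve w = chi*(einc + Md L w) per transmitter
    A = np.eye(n_d) - chi[:, None] * (Md @ L)
    W = np.linalg.solve(A, chi[:, None] * einc)
    f = Ms @ L @ W

    def c2l(a):
        a = np.asarray(a)
        return [a.real.tolist(), a.imag.tolist()]

    (out_dir / "toy_csi.json").write_text(json.dumps({
        "L": c2l(L), "Ms": c2l(Ms), "Md": c2l(Md),
        "einc": c2l(einc), "chi": c2l(chi), "W": c2l(W), "f": c2l(f),
    }))

    # Mie case
    from .forward import mie_cylinder_reference
    geo = AcquisitionGeometry.circular(domain_half_width=6.4, n_tx=8, n_rx=8)
    ref = mie_cylinder_reference(2.5, 30.0 - 3.0j, geo)
    (out_dir / "mie_case.json").write_text(json.dumps({
        "radius": 2.5, "eps_cyl": [30.0, -3.0], "domain_half_width": 6.4,
        "n_tx": 8, "n_rx": 8, "fields": c2l(ref),
    }))

    # small phantom
    prng = np.random.default_rng(7)
    phantom = ph.make_phantom("III", (32, 32), 0.35, prng, n_tumors=1)
    ph.save_phantom(out_dir / "phantom_32x32.h5", phantom)

    # ROC toy
    feats = [1.0, 2.0, 3.0, 4.0, 3.0, 5.0]
    labels = [0, 0, 0, 0, 1, 1]
    pairs = [(f_t, f_n) for f_t, l_t in zip(feats, labels) if l_t
             for f_n, l_n in zip(feats, labels) if not l_n]
    auc = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs) / len(pairs)
    (out_dir / "roc_toy.json").write_text(json.dumps({
        "features": feats, "labels": labels, "auc": auc,
    }))
    return out_dir
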