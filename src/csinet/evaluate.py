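"""Quantitative assessment: RMS error, pixel-wise ROC-AUC, cross-validation.

The evaluation mirrors the benchmark layout of the study this package
reproduces: a four-fold cross-validation over phantoms balanced per breast
model, four training settings differing in which breast models are seen
during training (A: I+II+III, B: I+II, C: I+III, D: II+III), and test
subsets drawn from the hold-out fold for every combination of breast
models (I, II, III, I&II, I&III, II&III and all three).  For every row the
report carries the RMS reconstruction error (real and imaginary parts
separately) and the pooled pixel-wise ROC-AUC with the reconstructed
permittivity part as the detection feature.  Raw CSI reconstructions are
evaluated on the same subsets as the baseline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import pixel_roc_auc, rms_error
from .unet import TrainConfig, UNetEnhancer, make_input_stack

#: breast models included in the training set per setting
SETTING_MODELS = {
    "A": ("I", "II", "III"),
    "B": ("I", "II"),
    "C": ("I", "III"),
    "D": ("II", "III"),
}

#: test subsets evaluated for every trained network
TEST_SUBSETS = {
    "all": ("I", "II", "III"),
    "I": ("I",),
    "II": ("II",),
    "III": ("III",),
    "I&II": ("I", "II"),
    "I&III": ("I", "III"),
    "II&III": ("II", "III"),
}

#: geometric stress transforms (name -> callable on (..., H, W) arrays)
TRANSFORMS = {
    "identity": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1, axes=(-2, -1)),
    "rot180": lambda a: np.rot90(a, 2, axes=(-2, -1)),
    "rot270": lambda a: np.rot90(a, 3, axes=(-2, -1)),
    "flip_h": lambda a: np.flip(a, axis=-1),
    "flip_v": lambda a: np.flip(a, axis=-2),
}


@dataclasses.dataclass
class ReconstructionBundle:
    """CSI reconstructions plus ground truth for a set of phantoms."""

    csi_real: np.ndarray      # (N, H, W)
    csi_imag: np.ndarray
    true_real: np.ndarray
    true_imag: np.ndarray
    tumor_masks: np.ndarray   # (N, H, W) bool
    eval_masks: np.ndarray    # (N, H, W) bool, breast interior
    model_ids: np.ndarray     # (N,) str
    folds: np.ndarray         # (N,) int
    snapshots: dict = dataclasses.field(default_factory=dict)
    # snapshots: iteration -> (csi_real, csi_imag) arrays

    @property
    def n(self):
        return self.csi_real.shape[0]

    def subset(self, idx):
        return ReconstructionBundle(
            csi_real=self.csi_real[idx], csi_imag=self.csi_imag[idx],
            true_real=self.true_real[idx], true_imag=self.true_imag[idx],
            tumor_masks=self.tumor_masks[idx], eval_masks=self.eval_masks[idx],
            model_ids=self.model_ids[idx], folds=self.folds[idx],
            snapshots={k: (v[0][idx], v[1][idx]) for k, v in self.snapshots.items()},
        )

    def input_stack(self, iteration=None):
        if iteration is None:
            return make_input_stack(self.csi_real, self.csi_imag)
        re, im = self.snapshots[iteration]
        return make_input_stack(re, im)


@dataclasses.dataclass
class EvalReport:
    """Tabulated metrics plus full ROC curves."""

    table: pd.DataFrame
    roc: dict = dataclasses.field(default_factory=dict)

    def to_files(self, out_dir, stem="report"):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        self.table.to_csv(csv_path, index=False)
        payload = {
            "table": self.table.to_dict(orient="records"),
            "roc": {
                "|".join(map(str, k)): {"fpr": v[0].tolist(), "tpr": v[1].tolist()}
                for k, v in self.roc.items()
            },
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(payload))
        return csv_path

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        roc = {
            tuple(k.split("|")): (np.asarray(v["fpr"]), np.asarray(v["tpr"]))
            for k, v in d["roc"].items()
        }
        return cls(table=pd.DataFrame(d["table"]), roc=roc)


def _metric_rows(pred_real, pred_imag, bundle, technique, setting, arch, roc,
                 subset_names=None):
    rows = []
    subset_names = subset_names or list(TEST_SUBSETS)
    for subset in subset_names:
        models = TEST_SUBSETS[subset]
        sel = np.isin(bundle.model_ids, models)
        if not sel.any():
            continue
        for part, pred in (("real", pred_real), ("imag", pred_imag)):
            truth = bundle.true_real if part == "real" else bundle.true_imag
            mask = bundle.eval_masks[sel]
            rms = rms_error(pred[sel], truth[sel], mask)
            auc, (fpr, tpr, _) = pixel_roc_auc(
                list(pred[sel]), list(bundle.tumor_masks[sel]),
                list(bundle.eval_masks[sel])
            )
            roc[(setting, technique, arch, part, subset)] = (fpr, tpr)
            rows.append({
                "setting": setting, "technique": technique,
                "architecture": arch, "part": part, "subset": subset,
                "rms": rms, "auc": auc,
                "n_phantoms": int(sel.sum()),
                "n_pixels": int(bundle.eval_masks[sel].sum()),
            })
    return rows


def evaluate_csi_baseline(bundle, roc=None, subset_names=None):
    """RMS and AUC of the raw CSI reconstructions per test subset."""
    roc = {} if roc is None else roc
    rows = _metric_rows(bundle.csi_real, bundle.csi_imag, bundle,
                        "CSI", "N/A", 0, roc, subset_names)
    return EvalReport(table=pd.DataFrame(rows), roc=roc)


def run_cross_validation(bundle: ReconstructionBundle, settings=("A",),
                         architecture=1, train_config: TrainConfig = None,
                         folds=None, subset_names=None):
    """Train per (setting, fold) and evaluate on the hold-out fold.

    Returns an :class:`EvalReport` whose rows aggregate the hold-out
    predictions of all requested folds, alongside the CSI baseline, plus
    the trained results of the last (setting, fold) pair for reuse.
    """
    cfg = train_config or TrainConfig(architecture=architecture)
    if cfg.architecture != architecture:
        cfg = dataclasses.replace(cfg, architecture=architecture)
    folds = sorted(set(bundle.folds)) if folds is None else list(folds)
    bad = [s for s in settings if s not in SETTING_MODELS]
    if bad:
        raise ValueError(f"unknown settings {bad}; valid: {list(SETTING_MODELS)}")

    roc = {}
    rows = evaluate_csi_baseline(bundle, roc, subset_names).table.to_dict("records")
    last_results = None
    for setting in settings:
        models = SETTING_MODELS[setting]
        preds_real = np.zeros_like(bundle.csi_real)
        preds_imag = np.zeros_like(bundle.csi_imag)
        tested = np.zeros(bundle.n, dtype=bool)
        for k in folds:
            train_sel = (bundle.folds != k) & np.isin(bundle.model_ids, models)
            test_sel = bundle.folds == k
            if not train_sel.any() or not test_sel.any():
                raise ValueError(f"empty train or test split for fold {k}")
            tr = bundle.subset(train_sel)
            enhancer = UNetEnhancer(tr.input_stack(), tr.true_real, tr.true_imag, cfg)
            results = enhancer.fit()
            te = bundle.subset(test_sel)
            pr, pi = results.predict(te.input_stack())
            preds_real[test_sel] = pr
            preds_imag[test_sel] = pi
            tested |= test_sel
            last_results = results
        sub = bundle.subset(tested)
        rows += _metric_rows(preds_real[tested], preds_imag[tested], sub,
                             f"U-Net {setting}", setting, cfg.architecture, roc,
                             subset_names)
    report = EvalReport(table=pd.DataFrame(rows), roc=roc)
    return report, last_results


def robustness_suite(results, bundle: ReconstructionBundle,
                     snapshot_iters=None, transforms=None):
    """Stress a trained network with early-stopped CSI inputs and
    geometric transforms; the CSI baseline is evaluated on the same
    transformed inputs.

    Returns an EvalReport with rows keyed by (snapshot iteration,
    transform, technique, part) on the all-models subset.
    """
    transforms = list(TRANSFORMS) if transforms is None else list(transforms)
    iters = sorted(bundle.snapshots) if snapshot_iters is None else list(snapshot_iters)
    rows = []
    roc = {}
    for it in iters:
        re_in, im_in = bundle.snapshots[it]
        for tname in transforms:
            tf = TRANSFORMS[tname]
            re_t, im_t = tf(re_in), tf(im_in)
            truth_r, truth_i = tf(bundle.true_real), tf(bundle.true_imag)
            tmask = tf(bundle.tumor_masks)
            emask = tf(bundle.eval_masks)
            stack = make_input_stack(re_t, im_t)
            pr, pi = results.predict(stack)
            for tech, (qr, qi) in (("U-Net", (pr, pi)), ("CSI", (re_t, im_t))):
                for part, q, tr_ in (("real", qr, truth_r), ("imag", qi, truth_i)):
                    rms = rms_error(q, tr_, emask)
                    auc, (fpr, tpr, _) = pixel_roc_auc(list(q), list(tmask), list(emask))
                    roc[(f"iter{it}", tech, tname, part, "all")] = (fpr, tpr)
                    rows.append({
                        "snapshot_iter": it, "transform": tname,
                        "technique": tech, "part": part,
                        "rms": rms, "auc": auc,
                    })
    return EvalReport(table=pd.DataFrame(rows), roc=roc)


def render_report(report: EvalReport, out_dir, stem="report", plot=True):
    """Write the CSV/JSON tables and ROC plot(s); returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [report.to_files(out_dir, stem)]
    paths.append(out_dir / f"{stem}.json")
    if plot and report.roc:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for key, (fpr, tpr) in list(report.roc.items())[:12]:
            ax.plot(fpr, tpr, lw=1, label="/".join(map(str, key)))
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend(fontsize=5, loc="lower right")
        fig.tight_layout()
        p = out_dir / f"{stem}_roc.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
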