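"""Two-step training scheme, evaluation protocol, and classical baselines.

Step 1a trains bi-modal classifiers (sMRI+fMRI and sMRI+SNP) on the CN/AD
subjects sharing the two channels, with stratified k-fold cross-validation
and weighted cross-entropy; the best fold by validation accuracy supplies
the encoders used to extract per-subject latent vectors. Step 1b trains
the two latent Cycle-GANs on those latents, keeping the same subjects per
mini-batch as the bi-modal training and validating imputation MAE on the
best fold's held-out subjects. Step 2 trains the full three-channel
framework with the four generators injected and frozen (audited by weight
checksum). Testing follows the reference protocol: an 80/20 stratified
CN/AD split for Task 1, the entire never-trained-on MCI cohort for Task 2
(MCIc as the patient class), accuracy/precision/recall from confusion
counts, and several independent reshuffled runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .config import RunConfig
from .cyclegan import CycleGANPair, evaluate_generator_mae, train_cyclegan
from .features import ModalityInputs
from .io import logger
from .models import (
    FusionClassifierSpec,
    FusionModel,
    build_encoder,
    build_head,
    group_by_mask,
    reference_encoder_spec,
    scaled_encoder_spec,
)
from .nn import Adam, weighted_cross_entropy

TASK1_POSITIVE = "AD"
TASK2_POSITIVE = "MCIc"
_CLASS01 = {"CN": 0, "AD": 1, "MCInc": 0, "MCIc": 1}


def labels01(inputs: list[ModalityInputs]) -> np.ndarray:
    """CN/MCInc -> 0, AD/MCIc -> 1 (patient class positive)."""
    return np.array([_CLASS01[mi.class_label] for mi in inputs])


def class_weights(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Inverse class frequency normalized to mean 1: w_c = N / (K * n_c)."""
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if np.any(counts == 0):
        raise ValueError("a class is absent from the training labels")
    return len(y) / (n_classes * counts)


# --- splits ---------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train ids, validation ids)
    seed: int

    def validate(self, labels_by_id: dict[str, str] | None = None) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test sets overlap")
        covered = set()
        for tr, va in self.folds:
            if set(tr) | set(va) != train or set(tr) & set(va):
                raise ValueError("folds do not partition the training set")
            covered |= set(va)
        if covered != train:
            raise ValueError("validation folds do not cover the training set")


def make_split(subjects, config: RunConfig, seed: int) -> SplitPlan:
    """Stratified train/test split plus stratified k-fold CV on the
    training portion. Fold count is reduced (with a warning) when the
    smallest class cannot fill the configured fold count."""
    ids = np.array([s.subject_id for s in subjects])
    labels = np.array([s.class_label for s in subjects])
    classes = set(labels)
    for cls in ("CN", "AD") if classes <= {"CN", "AD"} else classes:
        if cls not in classes:
            raise ValueError(f"class {cls} absent from cohort")
    tr_ids, te_ids = train_test_split(
        ids, test_size=config.test_fraction, stratify=labels, random_state=seed
    )
    tr_labels = labels[np.isin(ids, tr_ids)]
    tr_ids_ordered = ids[np.isin(ids, tr_ids)]
    min_class = min(np.bincount(np.unique(tr_labels, return_inverse=True)[1]))
    n_folds = min(config.n_folds, int(min_class))
    if n_folds < config.n_folds:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d subjects)",
            config.n_folds, n_folds, min_class,
        )
    if n_folds < 2:
        raise ValueError("not enough subjects per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        (list(tr_ids_ordered[tr]), list(tr_ids_ordered[va]))
        for tr, va in skf.split(tr_ids_ordered, tr_labels)
    ]
    return SplitPlan(
        train_ids=list(tr_ids_ordered), test_ids=list(te_ids), folds=folds, seed=seed
    )


# --- metrics --------------------------------------------------------------

@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def acc(self) -> float:
        n = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def pre(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def rec(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "MetricsReport":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if y_true.size == 0:
            raise ValueError("no subjects to evaluate")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    def as_dict(self) -> dict:
        return dict(acc=self.acc, pre=self.pre, rec=self.rec,
                    tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn)


def evaluate(model: FusionModel, inputs: list[ModalityInputs]) -> MetricsReport:
    """Accuracy/precision/recall with the patient class (AD or MCIc)
    positive; Task 2 reuses the Task-1-trained model without retraining."""
    if not inputs:
        raise ValueError("no subjects to evaluate")
    proba = model.predict_proba(inputs)
    return MetricsReport.from_predictions(labels01(inputs), proba.argmax(axis=1))


# --- model construction ---------------------------------------------------

def _encoder_spec(modality: str, config: RunConfig):
    if config.encoder_scale is None:
        return reference_encoder_spec(modality)
    pool = config.encoder_scale.get("pool", True)
    if isinstance(pool, dict):
        pool = pool.get(modality, True)
    return scaled_encoder_spec(
        modality,
        width=config.encoder_scale.get("width", 8),
        fc_width=config.encoder_scale.get("fc_width", 32),
        pool=pool,
    )


def build_fusion_model(
    modalities: list[str],
    config: RunConfig,
    rng: np.random.Generator,
    generators: dict | None = None,
) -> FusionModel:
    encoders = {
        m: build_encoder(m, _encoder_spec(m, config), config, rng) for m in modalities
    }
    head = build_head(
        FusionClassifierSpec(n_channels=len(modalities)), config.latent_dim, rng
    )
    return FusionModel(encoders, head, config, generators=generators)


# --- shared training loop -------------------------------------------------

def _fixed_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _train_epochs(
    model: FusionModel,
    inputs: list[ModalityInputs],
    y: np.ndarray,
    batches: list[np.ndarray],
    epochs: int,
    config: RunConfig,
) -> list[float]:
    w = class_weights(y)
    opt = Adam(model.trainable_params(), lr=config.learning_rate)
    losses = []
    for _ in range(epochs):
        total = 0.0
        for bt in batches:
            sub = [inputs[i] for i in bt]
            yb = y[bt]
            model.zero_grad()
            for gidx, gsub in group_by_mask(sub):
                logits, _ = model.forward_routed(gsub, train=True)
                loss, grad = weighted_cross_entropy(logits, yb[gidx], w)
                scale = len(gidx) / len(bt)
                model.backward_routed(grad * scale)
                total += loss * scale
            opt.step()
        losses.append(total / max(len(batches), 1))
    return losses


def _val_metrics(model, inputs, idx, y) -> tuple[float, float]:
    sub = [inputs[i] for i in idx]
    proba = model.predict_proba(sub)
    acc = float(np.mean(proba.argmax(axis=1) == y[idx]))
    eps = 1e-12
    nll = float(np.mean(-np.log(np.clip(proba[np.arange(len(idx)), y[idx]], eps, None))))
    return acc, nll


@dataclass
class CVResult:
    model: FusionModel
    best_fold: int
    fold_accuracy: list[float]
    fold_loss: list[float]
    best_batches_ids: list[list[str]]  # subject ids per mini-batch, best fold
    best_val_ids: list[str]
    train_losses: list[float] = field(default_factory=list)


def _crossval_train(
    modalities: list[str],
    inputs: list[ModalityInputs],
    config: RunConfig,
    seed: int,
    batch_size: int,
    epochs: int,
    generators: dict | None = None,
) -> CVResult:
    """Stratified CV; the best fold's model (by validation accuracy, ties
    broken by lower validation loss, then lower fold index) is returned."""
    y = labels01(inputs)
    plan = make_split_folds_only(inputs, config, seed)
    id_to_idx = {mi.subject_id: i for i, mi in enumerate(inputs)}
    best = None
    for k, (tr_ids, va_ids) in enumerate(plan):
        rng = np.random.default_rng((seed + 1) * 1000 + k)
        model = build_fusion_model(modalities, config, rng, generators=generators)
        tr_idx = np.array([id_to_idx[i] for i in tr_ids])
        va_idx = np.array([id_to_idx[i] for i in va_ids])
        batches = [tr_idx[b] for b in _fixed_batches(len(tr_idx), batch_size, rng)]
        losses = _train_epochs(model, inputs, y, batches, epochs, config)
        acc, nll = _val_metrics(model, inputs, va_idx, y)
        entry = (acc, -nll, -k)
        if best is None or entry > best[0]:
            best = (entry, model, k, batches, va_ids, losses)
        if best is None:
            raise RuntimeError("no folds trained")
        logger.info("fold %d: val acc %.3f, val nll %.3f", k, acc, nll)
        if k == 0:
            fold_acc, fold_nll = [acc], [nll]
        else:
            fold_acc.append(acc)
            fold_nll.append(nll)
    _, model, kbest, batches, va_ids, losses = best
    batch_ids = [[inputs[i].subject_id for i in b] for b in batches]
    return CVResult(
        model=model,
        best_fold=kbest,
        fold_accuracy=fold_acc,
        fold_loss=fold_nll,
        best_batches_ids=batch_ids,
        best_val_ids=list(va_ids),
        train_losses=losses,
    )


def make_split_folds_only(inputs, config: RunConfig, seed: int):
    """Stratified k-fold assignments over the given subjects (no test split)."""
    ids = np.array([mi.subject_id for mi in inputs])
    y = labels01(inputs)
    counts = np.bincount(y, minlength=2)
    if np.any(counts == 0):
        raise ValueError("both classes must be present for cross-validation")
    n_folds = min(config.n_folds, int(counts.min()))
    if n_folds < config.n_folds:
        logger.warning("reducing CV folds from %d to %d", config.n_folds, n_folds)
    if n_folds < 2:
        raise ValueError("not enough subjects per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(list(ids[tr]), list(ids[va])) for tr, va in skf.split(ids, y)]


# --- Step 1a: bi-modal models --------------------------------------------

BIMODAL_PAIRS = {
    "smri-fmri": ("smri", "fmri"),
    "smri-snp": ("smri", "snp"),
}


def train_bimodal(
    pair: str, inputs: list[ModalityInputs], config: RunConfig, seed: int
) -> CVResult:
    """Train one bi-modal model on CN/AD subjects sharing both channels."""
    if pair not in BIMODAL_PAIRS:
        raise ValueError(f"unknown bi-modal pair {pair!r}")
    mods = list(BIMODAL_PAIRS[pair])
    usable = [
        mi for mi in inputs
        if mi.class_label in ("CN", "AD") and all(dict(zip(("smri", "fmri", "snp"), mi.mask()))[m] for m in mods)
    ]
    if not usable:
        raise ValueError(f"no CN/AD subjects share modalities {mods}")
    batch = config.batch_smri_fmri if pair == "smri-fmri" else config.batch_smri_snp
    return _crossval_train(mods, usable, config, seed, batch, config.epochs_bimodal)


def extract_latents(
    model: FusionModel, inputs: list[ModalityInputs], modality: str
) -> tuple[list[str], np.ndarray]:
    """Encode one modality for every subject (which must have it)."""
    attr = {"smri": "volume", "fmri": "fnc", "snp": "snp"}[modality]
    missing = [mi.subject_id for mi in inputs if getattr(mi, attr) is None]
    if missing:
        raise ValueError(f"subjects missing {modality}: {missing[:3]}...")
    x = np.stack([getattr(mi, attr) for mi in inputs])[:, None, ...]
    z = model.encoders[modality].forward(x, train=False)
    return [mi.subject_id for mi in inputs], z


# --- Step 1b + 2: generators and the full framework ----------------------

@dataclass
class FullResult:
    cv: CVResult
    generator_checksums_before: dict[str, float]
    generator_checksums_after: dict[str, float]


def train_full(
    inputs: list[ModalityInputs],
    pairs: dict[str, CycleGANPair],
    config: RunConfig,
    seed: int,
) -> FullResult:
    """Step 2: train encoders + fusion head with frozen generators.

    ``pairs`` maps "smri-fmri" / "smri-snp" to trained Cycle-GAN pairs.
    MCI subjects must not appear in ``inputs``. Generator weights are
    checksummed before and after; any drift is a hard failure.
    """
    if any(mi.class_label not in ("CN", "AD") for mi in inputs):
        raise ValueError("Step-2 training cohort must contain CN and AD only")
    generators = {}
    for name, pair in pairs.items():
        a, b = BIMODAL_PAIRS[name]
        generators[(a, b)] = pair.bridge(a, b)
        generators[(b, a)] = pair.bridge(b, a)
    before = {
        name: float(sum(pair.generator_checksums())) for name, pair in pairs.items()
    }
    cv = _crossval_train(
        ["smri", "fmri", "snp"], inputs, config, seed,
        config.batch_full, config.epochs_full, generators=generators,
    )
    after = {
        name: float(sum(pair.generator_checksums())) for name, pair in pairs.items()
    }
    for name in pairs:
        if before[name] != after[name]:
            raise RuntimeError(
                f"frozen generator weights drifted during Step-2 training ({name})"
            )
    return FullResult(cv=cv, generator_checksums_before=before,
                      generator_checksums_after=after)


# --- baselines ------------------------------------------------------------

def _flat_features(inputs: list[ModalityInputs], config: RunConfig) -> np.ndarray:
    n_vol = int(np.prod(config.volume_shape))
    rows = []
    for mi in inputs:
        vol = mi.volume.ravel() if mi.volume is not None else np.full(n_vol, np.nan)
        fnc = mi.fnc if mi.fnc is not None else np.full(config.n_fnc_features, np.nan)
        snp = mi.snp if mi.snp is not None else np.full(config.n_snps, np.nan)
        rows.append(np.concatenate([vol, fnc, snp]))
    return np.array(rows)


def run_baselines(
    train_inputs: list[ModalityInputs],
    test_inputs: list[ModalityInputs],
    mci_inputs: list[ModalityInputs],
    config: RunConfig,
    seed: int,
) -> dict[str, dict[str, MetricsReport]]:
    """Ensemble SVM and random-forest baselines with mean/zero imputation.

    Imputation constants are fitted on the training rows only; the same
    fitted pipeline scores the Task-1 test set and the MCI cohort.
    """
    x_train = _flat_features(train_inputs, config)
    y_train = labels01(train_inputs)
    x_test = _flat_features(test_inputs, config)
    x_mci = _flat_features(mci_inputs, config) if mci_inputs else None

    out: dict[str, dict[str, MetricsReport]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN training columns
        col_mean = np.nanmean(x_train, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    for impute in ("mean", "zero"):
        fill = col_mean if impute == "mean" else np.zeros(x_train.shape[1])
        xtr = np.where(np.isnan(x_train), fill, x_train)
        xte = np.where(np.isnan(x_test), fill, x_test)
        for name, clf in (
            ("svm", BaggingClassifier(SVC(), n_estimators=10, random_state=seed)),
            ("rf", RandomForestClassifier(n_estimators=10, random_state=seed)),
        ):
            clf.fit(xtr, y_train)
            key = f"{name}-{impute}"
            out[key] = {
                "task1": MetricsReport.from_predictions(
                    labels01(test_inputs), clf.predict(xte)
                )
            }
            if x_mci is not None and len(mci_inputs):
                xm = np.where(np.isnan(x_mci), fill, x_mci)
                out[key]["task2"] = MetricsReport.from_predictions(
                    labels01(mci_inputs), clf.predict(xm)
                )
    return out


# --- end-to-end experiment ------------------------------------------------

@dataclass
class ExperimentResult:
    seed: int
    split: SplitPlan
    bimodal_fmri: CVResult
    bimodal_snp: CVResult
    pair_sf: CycleGANPair
    pair_sg: CycleGANPair
    full: FullResult
    task1: MetricsReport
    task2: MetricsReport | None
    generator_mae: dict[str, float]
    baselines: dict[str, dict[str, MetricsReport]] | None = None


def run_experiment(
    inputs: list[ModalityInputs],
    config: RunConfig,
    seed: int,
    with_baselines: bool = False,
    cgan_generator_hidden=None,
) -> ExperimentResult:
    """One full run: Step 1a, 1b, 2, then Task-1 and Task-2 evaluation."""
    from .cyclegan import GENERATOR_HIDDEN

    cn_ad = [mi for mi in inputs if mi.class_label in ("CN", "AD")]
    mci = [mi for mi in inputs if mi.class_label in ("MCInc", "MCIc")]
    split = make_split(cn_ad, config, seed)
    by_id = {mi.subject_id: mi for mi in inputs}
    train_set = [by_id[i] for i in split.train_ids]
    test_set = [by_id[i] for i in split.test_ids]

    # Step 1a
    bf = train_bimodal("smri-fmri", train_set, config, seed)
    bg = train_bimodal("smri-snp", train_set, config, seed + 17)

    gen_hidden = cgan_generator_hidden or GENERATOR_HIDDEN

    # Step 1b: latents from the best bi-modal models; cGAN batches reuse the
    # bi-modal batch composition, validation on the best fold's held-out ids
    pairs = {}
    for name, cvres, dst in (("smri-fmri", bf, "fmri"), ("smri-snp", bg, "snp")):
        usable = [
            mi for mi in train_set
            if mi.class_label in ("CN", "AD")
            and (mi.volume is not None)
            and (getattr(mi, "fnc" if dst == "fmri" else "snp") is not None)
        ]
        ids, z_s = extract_latents(cvres.model, usable, "smri")
        _, z_d = extract_latents(cvres.model, usable, dst)
        id_to_row = {sid: i for i, sid in enumerate(ids)}
        batches = [
            np.array([id_to_row[s] for s in bt if s in id_to_row])
            for bt in cvres.best_batches_ids
        ]
        batches = [b for b in batches if len(b)]
        val_idx = np.array([id_to_row[s] for s in cvres.best_val_ids if s in id_to_row])
        pairs[name] = train_cyclegan(
            z_s, z_d, config, domain_a="smri", domain_b=dst,
            batches=batches, val_indices=val_idx if len(val_idx) else None,
            generator_hidden=gen_hidden, seed=seed + 31,
        )

    # Step 2
    full = train_full(train_set, pairs, config, seed + 47)

    task1 = evaluate(full.cv.model, test_set)
    task2 = evaluate(full.cv.model, mci) if mci else None

    mae = {}
    for name, pair in pairs.items():
        hist = pair.history[-1] if pair.history else None
        if hist and hist.val_mae_ab is not None:
            a, b = BIMODAL_PAIRS[name]
            mae[f"{a}->{b}"] = hist.val_mae_ab
            mae[f"{b}->{a}"] = hist.val_mae_ba

    baselines = (
        run_baselines(train_set, test_set, mci, config, seed) if with_baselines else None
    )
    return ExperimentResult(
        seed=seed, split=split, bimodal_fmri=bf, bimodal_snp=bg,
        pair_sf=pairs["smri-fmri"], pair_sg=pairs["smri-snp"], full=full,
        task1=task1, task2=task2, generator_mae=mae, baselines=baselines,
    )


def run_generalization(
    inputs: list[ModalityInputs],
    config: RunConfig,
    seeds: list[int] | None = None,
    with_baselines: bool = False,
    cgan_generator_hidden=None,
) -> dict:
    """Independent reshuffled runs; per-run and mean +/- sd metrics."""
    if seeds is None:
        seeds = [config.seed + i for i in range(config.n_runs)]
    runs = [
        run_experiment(inputs, config, s, with_baselines=with_baselines,
                       cgan_generator_hidden=cgan_generator_hidden)
        for s in seeds
    ]
    def agg(vals):
        vals = np.array(vals, dtype=float)
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0)),
                "runs": vals.tolist()}
    out = {
        "seeds": list(seeds),
        "task1": {m: agg([getattr(r.task1, m) for r in runs]) for m in ("acc", "pre", "rec")},
        "runs": runs,
    }
    if all(r.task2 is not None for r in runs):
        out["task2"] = {m: agg([getattr(r.task2, m) for r in runs]) for m in ("acc", "pre", "rec")}
    return out
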