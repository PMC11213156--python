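"""Integrated-Gradients attribution and its statistical validation.

For input x and baseline x', Integrated Gradients assigns feature i

    IG_i = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF(x' + (k/m)(x - x')) / dx_i

a right-Riemann discretization of the path integral of model gradients
along the straight line from x' to x. It satisfies the completeness axiom
sum_i IG_i -> F(x) - F(x') as m grows; the residual is recorded per
subject. Baselines follow the channel semantics: an all-zero volume
(no gray matter), an all-zero connectivity vector (no coupling), and a
fixed Gaussian-noise dosage vector (no informative genotype).

Downstream, attributions are thresholded per map (99.5th percentile of
absolute values voxelwise for sMRI, 98th connection-wise for fMRI, 65th
for SNPs with the extra positivity requirement), aggregated over atlas
regions with a subject-retention rule, mapped to resting-state-network
connectograms, and compared across the four diagnostic groups with
Kruskal-Wallis gating pairwise Wilcoxon rank-sum tests under Bonferroni
correction (six contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import ModalityInputs, NetworkPartition, upper_triangle_index_pairs
from .io import ValidationError, logger
from .models import FusionModel
from .nn import softmax

CONTRASTS = (
    ("AD", "CN"),
    ("AD", "MCIc"),
    ("AD", "MCInc"),
    ("CN", "MCIc"),
    ("CN", "MCInc"),
    ("MCIc", "MCInc"),
)


@dataclass
class IGConfig:
    n_steps: int = 64
    target: str = "logit"  # "logit" | "probability", of the predicted class
    snp_baseline: np.ndarray | None = None  # Gaussian noise vector, drawn once per run

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.target not in ("logit", "probability"):
            raise ValueError(f"unknown target {self.target!r}")


def make_ig_config(n_snps: int, seed: int, n_steps: int = 64, target: str = "logit") -> IGConfig:
    """Baseline triplet with the SNP Gaussian baseline drawn from a
    dedicated seed and reused for every subject of the run."""
    rng = np.random.default_rng(seed)
    return IGConfig(n_steps=n_steps, target=target, snp_baseline=rng.standard_normal(n_snps))


@dataclass
class AttributionSet:
    subject_id: str
    class_label: str
    smri: np.ndarray
    fmri: np.ndarray
    snp: np.ndarray
    predicted_class: int
    correct: bool
    completeness_residual: float
    delta_f: float


def integrated_gradients(
    model: FusionModel, x: ModalityInputs, igcfg: IGConfig, true_label_index: int | None = None
) -> AttributionSet:
    """Joint attribution over the three channels along one straight path."""
    if x.volume is None or x.fnc is None or x.snp is None:
        raise ValidationError(
            f"{x.subject_id}: Integrated Gradients requires all three channels"
        )
    if igcfg.snp_baseline is None:
        raise ValueError("IGConfig.snp_baseline is not set")
    if igcfg.snp_baseline.shape != x.snp.shape:
        raise ValueError("SNP baseline shape does not match input")

    inputs = {"smri": x.volume, "fmri": x.fnc, "snp": x.snp}
    baselines = {
        "smri": np.zeros_like(x.volume),
        "fmri": np.zeros_like(x.fnc),
        "snp": np.asarray(igcfg.snp_baseline, dtype=np.float64),
    }

    # prediction at the input fixes the attribution target
    point = {m: inputs[m][None, None, ...] for m in model.modalities}
    logits_x = model.forward_arrays(point, train=False)
    target = int(np.argmax(logits_x[0]))
    logits_base = model.forward_arrays(
        {m: baselines[m][None, None, ...] for m in model.modalities}, train=False
    )

    m_steps = igcfg.n_steps
    alphas = (np.arange(1, m_steps + 1) / m_steps).reshape((-1,) + (1,) * 1)

    batch = {}
    for mod in model.modalities:
        diff = inputs[mod] - baselines[mod]
        a = alphas.reshape((-1,) + (1,) * inputs[mod].ndim)
        batch[mod] = (baselines[mod] + a * diff)[:, None, ...]

    logits = model.forward_arrays(batch, train=False)
    if igcfg.target == "logit":
        dlogits = np.zeros_like(logits)
        dlogits[:, target] = 1.0
        f_x = float(logits_x[0, target])
        f_base = float(logits_base[0, target])
    else:
        probs = softmax(logits)
        dlogits = -probs * probs[:, [target]]
        dlogits[:, target] += probs[:, target]
        f_x = float(softmax(logits_x)[0, target])
        f_base = float(softmax(logits_base)[0, target])
    grads = model.backward_arrays(dlogits)

    attributions = {}
    for mod in model.modalities:
        g = grads[mod][:, 0, ...]  # (m, ...)
        if not np.all(np.isfinite(g)):
            bad = int(np.flatnonzero(~np.isfinite(g).reshape(m_steps, -1).all(axis=1))[0])
            raise FloatingPointError(f"non-finite gradient at path index {bad}")
        attributions[mod] = (inputs[mod] - baselines[mod]) * g.mean(axis=0)

    total = sum(float(a.sum()) for a in attributions.values())
    delta_f = f_x - f_base
    residual = total - delta_f
    correct = true_label_index is None or target == true_label_index
    return AttributionSet(
        subject_id=x.subject_id,
        class_label=x.class_label,
        smri=attributions["smri"],
        fmri=attributions["fmri"],
        snp=attributions["snp"],
        predicted_class=target,
        correct=bool(correct),
        completeness_residual=float(residual),
        delta_f=float(delta_f),
    )


# --- thresholding --------------------------------------------------------

def threshold_attributions(
    attribution: np.ndarray, percentile: float, mode: str = "absolute"
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the flattened map) and values surviving the rule.

    ``absolute``: |v| strictly exceeds the given percentile of the |v|
    distribution of this map. ``positive``: additionally v > 0.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0,100), got {percentile}")
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown mode {mode!r}")
    flat = np.asarray(attribution, dtype=np.float64).ravel()
    if flat.size == 0:
        raise ValueError("empty attribution map")
    cut = np.percentile(np.abs(flat), percentile)
    keep = np.abs(flat) > cut
    if mode == "positive":
        keep &= flat > 0
    idx = np.flatnonzero(keep)
    return idx, flat[idx]


def threshold_map(attribution: np.ndarray, percentile: float, mode: str = "absolute") -> np.ndarray:
    """Same rule, returned as a map with non-survivors zeroed."""
    idx, vals = threshold_attributions(attribution, percentile, mode)
    out = np.zeros(attribution.size)
    out[idx] = vals
    return out.reshape(np.asarray(attribution).shape)


def aggregate_regions(
    thresholded_maps: list[np.ndarray],
    atlas_labels: np.ndarray,
    retention_fraction: float = 0.99,
) -> tuple[pd.DataFrame, list[int]]:
    """Region means of surviving attributions, and the retained regions.

    For each subject and atlas region, the mean of that subject's surviving
    (nonzero after thresholding) attribution values inside the region, NaN
    when nothing survived there. A region is retained when at least
    ``retention_fraction`` of subjects have a surviving average in it.
    """
    atlas = np.asarray(atlas_labels)
    regions = sorted(int(r) for r in np.unique(atlas) if r != 0)
    if not regions:
        raise ValueError("atlas contains no foreground labels")
    rows = []
    for m in thresholded_maps:
        m = np.asarray(m)
        if m.shape != atlas.shape:
            raise ValueError(f"map shape {m.shape} != atlas shape {atlas.shape}")
        row = {}
        for r in regions:
            vals = m[atlas == r]
            vals = vals[vals != 0]
            row[r] = vals.mean() if vals.size else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    frac = table.notna().mean(axis=0)
    retained = [int(r) for r in regions if frac[r] >= retention_fraction]
    return table, retained


def region_means(attribution: np.ndarray, atlas_labels: np.ndarray, region: int) -> float:
    atlas = np.asarray(atlas_labels)
    if not np.any(atlas == region):
        raise ValueError(f"label {region} absent from atlas")
    return float(np.asarray(attribution)[atlas == region].mean())


# --- connectogram --------------------------------------------------------

def build_connectogram(
    fnc_attribution: np.ndarray,
    partition: NetworkPartition,
    percentile: float = 98.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Surviving connections mapped back to component pairs and networks.

    Returns an edge table (component ids, network labels, attribution,
    intra/inter flag) and, per network, the percentage of surviving edges
    with at least one endpoint in that network.
    """
    vec = np.asarray(fnc_attribution, dtype=np.float64).ravel()
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if vec.size != n * (n - 1) // 2:
        raise ValueError(f"attribution length {vec.size} is not n(n-1)/2")
    pairs = upper_triangle_index_pairs(n)
    idx, vals = threshold_attributions(vec, percentile, mode="absolute")
    records = []
    for k, v in zip(idx, vals):
        i, j = (int(c) for c in pairs[k])
        rsn_i, rsn_j = partition.network_of(i), partition.network_of(j)
        records.append(
            dict(
                component_i=i,
                component_j=j,
                network_i=rsn_i,
                network_j=rsn_j,
                value=float(v),
                kind="intra" if rsn_i == rsn_j else "inter",
            )
        )
    edges = pd.DataFrame(
        records,
        columns=["component_i", "component_j", "network_i", "network_j", "value", "kind"],
    )
    summary: dict[str, float] = {}
    n_edges = len(edges)
    networks = sorted(set(partition.assignment.values()))
    for net in networks:
        if n_edges == 0:
            summary[net] = 0.0
        else:
            touch = ((edges.network_i == net) | (edges.network_j == net)).sum()
            summary[net] = 100.0 * touch / n_edges
    return edges, summary


def select_snps(snp_attribution: np.ndarray, percentile: float = 65.0) -> list[int]:
    """SNPs with positive attribution strictly above the percentile of the
    absolute attribution distribution, sorted by descending attribution."""
    vec = np.asarray(snp_attribution, dtype=np.float64).ravel()
    idx, vals = threshold_attributions(vec, percentile, mode="positive")
    order = np.argsort(-vals)
    return [int(i) for i in idx[order]]


# --- group statistics ----------------------------------------------------

@dataclass
class GroupStatsReport:
    feature_names: list[str]
    shapiro_p: dict[str, float]
    kruskal: dict[str, tuple[float, float]]  # feature -> (H, p)
    pairwise: dict[str, dict[str, tuple[float, float]]]  # feature -> contrast -> (raw, adj)
    skipped: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "features": self.feature_names,
            "shapiro_p": self.shapiro_p,
            "kruskal": {k: list(v) for k, v in self.kruskal.items()},
            "pairwise": {
                f: {c: list(v) for c, v in d.items()} for f, d in self.pairwise.items()
            },
            "skipped": self.skipped,
        }


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small samples)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def group_stats(
    feature_table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    bonferroni_family: str = "contrasts",
) -> GroupStatsReport:
    """Four-group nonparametric comparison per feature.

    Shapiro-Wilk normality p-values are reported (diagnostic only; the
    pipeline is nonparametric regardless). Kruskal-Wallis across the four
    groups at ``alpha`` gates the six pairwise rank-sum contrasts, which
    are Bonferroni-adjusted (family = 6 contrasts by default, or
    contrasts x features with ``bonferroni_family='all'``).
    """
    if isinstance(feature_table, np.ndarray):
        feature_table = pd.DataFrame(
            feature_table, columns=[f"f{i}" for i in range(feature_table.shape[1])]
        )
    labels = np.asarray(labels)
    if len(labels) != len(feature_table):
        raise ValueError("labels length does not match table rows")
    groups = ("CN", "AD", "MCInc", "MCIc")
    features = list(feature_table.columns)
    family = 6 if bonferroni_family == "contrasts" else 6 * len(features)

    shapiro_p: dict[str, float] = {}
    kruskal: dict[str, tuple[float, float]] = {}
    pairwise: dict[str, dict[str, tuple[float, float]]] = {}
    skipped: list[str] = []

    for feat in features:
        col = feature_table[feat].to_numpy(dtype=np.float64)
        per_group = {g: col[(labels == g) & ~np.isnan(col)] for g in groups}
        if any(len(v) < 3 for v in per_group.values()):
            logger.warning("feature %s skipped: a group has < 3 observations", feat)
            skipped.append(str(feat))
            continue
        pooled = col[~np.isnan(col)]
        if np.ptp(pooled) == 0:
            shapiro_p[str(feat)] = 1.0
            kruskal[str(feat)] = (0.0, 1.0)
            continue
        shapiro_p[str(feat)] = float(stats.shapiro(pooled).pvalue)
        samples = [per_group[g] for g in groups]
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:  # all values identical across groups
            h, p = 0.0, 1.0
        kruskal[str(feat)] = (float(h), float(p))
        if p < alpha:
            contrasts = {}
            for g1, g2 in CONTRASTS:
                raw = rank_sum_test(per_group[g1], per_group[g2])
                contrasts[f"{g1}-{g2}"] = (raw, bonferroni(raw, family))
            pairwise[str(feat)] = contrasts

    return GroupStatsReport(
        feature_names=[str(f) for f in features],
        shapiro_p=shapiro_p,
        kruskal=kruskal,
        pairwise=pairwise,
        skipped=skipped,
        alpha=alpha,
    )
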