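"""Synthetic paired two-platform expression cohorts.

The generator emulates the gold-standard design for benchmarking
cross-platform normalization: the same biological samples measured on two
technologies (e.g. microarray and RNA-seq).  A latent log2-scale signal

    z_ij = baseline_j + class_effect_ij + biological_noise_ij

carries the biology: per-gene baselines, K subtype classes driven by mean
shifts in a subset of signature genes, and sample-to-sample biological
variation shared by both platforms.  Signature effects are *signed*, with a
class-specific balance of up- versus down-regulated markers (evenly spaced
from all-up to all-down across classes by default).  The asymmetry matters:
real subtype programs are unbalanced, and it is exactly this imbalance that
makes raw cross-platform transfer fail — with perfectly symmetric all-up
signatures, the per-class score offsets a platform shift induces in a
linear classifier cancel, and the log2 negative control would spuriously
succeed.

Platform A observes ``z`` plus measurement noise — a log-abundance
technology such as RNA-seq log2 counts.  Platform B observes a per-gene
monotone distortion

    g_j(z) = a_j + b_j * (z - c * m_j) + nonlinearity_strength * h(z - c * m_j)

plus its own measurement noise, where the location shifts ``a_j`` are
Gaussian, the scale factors ``b_j`` are uniform on a positive interval,
``m_j`` is the gene baseline, and ``c`` (``platform_b_centering``, default
1) makes platform B a *ratio-type* technology reporting values centered
near zero per gene — the convention of two-colour microarray log-ratios.
This coherent displacement of every gene, interacting with unbalanced
signatures, is what collapses raw cross-platform predictions.  ``h`` is a
fixed smooth saturating curve (``4 * tanh(. / 4)``) mimicking the
compressed dynamic range of array intensities relative to sequencing.
Because ``g_j`` is strictly increasing, a per-gene quantile map can in
principle invert the platform effect, and when the distortion is purely
affine a per-gene mean/SD match inverts it exactly.

All randomness flows from one seed through independent spawned streams, so
draws for one component do not perturb another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ExpressionMatrix, LabelVector

__all__ = ["SimulationConfig", "PairedCohort", "simulate_paired_cohort", "split_cohort"]

#: fixed smooth monotone saturation used for the nonlinear distortion term
def _saturating(z: np.ndarray) -> np.ndarray:
    return 4.0 * np.tanh(z / 4.0)


@dataclass(frozen=True)
class SimulationConfig:
    """World description for a paired-platform cohort.

    Defaults are a desk-scale surrogate for a dual-platform tumour cohort:
    a few hundred samples, a couple of thousand genes, four imbalanced
    subtypes, 10% signature genes with a 1.5 log2-unit class shift, and a
    strong per-gene platform distortion (ratio-type platform B, location
    shift SD 2, scale 0.5-2).

    ``signature_up_fractions`` sets, per class, the fraction of that
    class's signature genes that are up- (rather than down-) regulated;
    ``None`` spaces the fractions evenly from 1 to 0 across classes.
    """

    n_samples: int = 200
    p_genes: int = 2000
    k_classes: int = 4
    class_proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    signature_fraction: float = 0.1
    class_effect_size: float = 1.5  # log2 units
    signature_up_fractions: tuple[float, ...] | None = None
    platform_shift_sd: float = 2.0
    platform_scale_range: tuple[float, float] = (0.5, 2.0)
    platform_b_centering: float = 1.0  # 1 = ratio-type platform B, 0 = absolute
    nonlinearity_strength: float = 0.0
    noise_sd: float = 0.5  # per-platform measurement noise
    biological_sd: float = 1.0  # sample-to-sample variation shared by platforms
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4 * self.k_classes:
            raise ValueError("n_samples must be at least 4 * k_classes")
        if self.p_genes < 10:
            raise ValueError("p_genes must be ≥ 10")
        if self.k_classes < 2:
            raise ValueError("k_classes must be ≥ 2")
        if len(self.class_proportions) != self.k_classes:
            raise ValueError("class_proportions length must equal k_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-8 or min(self.class_proportions) <= 0:
            raise ValueError("class_proportions must be positive and sum to 1")
        if not 0.0 <= self.signature_fraction <= 1.0:
            raise ValueError("signature_fraction must lie in [0, 1]")
        lo, hi = self.platform_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("platform_scale_range must be a positive interval")
        if self.nonlinearity_strength < 0 or self.noise_sd < 0 or self.platform_shift_sd < 0:
            raise ValueError("noise and distortion magnitudes must be non-negative")
        if not 0.0 <= self.platform_b_centering <= 1.0:
            raise ValueError("platform_b_centering must lie in [0, 1]")
        if self.signature_up_fractions is not None:
            if len(self.signature_up_fractions) != self.k_classes:
                raise ValueError("signature_up_fractions length must equal k_classes")
            if any(not 0.0 <= u <= 1.0 for u in self.signature_up_fractions):
                raise ValueError("signature_up_fractions must lie in [0, 1]")

    def up_fractions(self) -> tuple[float, ...]:
        if self.signature_up_fractions is not None:
            return self.signature_up_fractions
        K = self.k_classes
        return tuple((K - 1 - c) / (K - 1) for c in range(K))


@dataclass
class PairedCohort:
    """Two platforms over identical samples and genes, with ground truth."""

    platform_a: ExpressionMatrix
    platform_b: ExpressionMatrix
    labels: LabelVector
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform_a.sample_ids != self.platform_b.sample_ids:
            raise ValueError("platforms must share identical sample_ids")
        if self.platform_a.gene_ids != self.platform_b.gene_ids:
            raise ValueError("platforms must share identical gene_ids")
        if self.labels.sample_ids != self.platform_a.sample_ids:
            raise ValueError("labels must cover the cohort samples in order")

    @property
    def n_samples(self) -> int:
        return self.platform_a.n_samples

    @property
    def n_genes(self) -> int:
        return self.platform_a.n_genes

    def subset(self, idx) -> "PairedCohort":
        idx = list(idx)
        return PairedCohort(
            self.platform_a.subset_samples(idx),
            self.platform_b.subset_samples(idx),
            self.labels.subset(idx),
            dict(self.truth),
        )

    def swapped(self) -> "PairedCohort":
        """The same cohort with the two platforms exchanged."""
        return PairedCohort(self.platform_b, self.platform_a, self.labels, dict(self.truth))


def _class_sizes(n: int, proportions: tuple[float, ...]) -> list[int]:
    # largest-remainder apportionment; every class keeps ≥1 member
    raw = [p * n for p in proportions]
    sizes = [max(1, math.floor(r)) for r in raw]
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - math.floor(raw[i]), reverse=True)
    i = 0
    while sum(sizes) < n:
        sizes[remainders[i % len(raw)]] += 1
        i += 1
    while sum(sizes) > n:
        j = max(range(len(sizes)), key=lambda c: sizes[c])
        sizes[j] -= 1
    return sizes


def simulate_paired_cohort(config: SimulationConfig) -> PairedCohort:
    """Draw one paired cohort from the configured world; reproducible from seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_base, rng_label, rng_sig, rng_bio, rng_plat, rng_na, rng_nb = (
        np.random.Generator(np.random.Philox(s)) for s in streams
    )

    n, p, K = config.n_samples, config.p_genes, config.k_classes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{j + 1:05d}" for j in range(p)]
    class_names = [f"subtype{c + 1}" for c in range(K)]

    sizes = _class_sizes(n, config.class_proportions)
    label_idx = np.repeat(np.arange(K), sizes)
    rng_label.shuffle(label_idx)
    labels = LabelVector(sample_ids, [class_names[c] for c in label_idx])

    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=p)

    n_sig = int(round(config.signature_fraction * p))
    sig_idx = rng_sig.choice(p, size=n_sig, replace=False) if n_sig else np.array([], dtype=int)
    sig_class = np.arange(n_sig) % K  # round-robin: each class gets its own signature genes
    up = config.up_fractions()
    # per class, the first round(up_c * s_c) of its s_c signature genes are
    # up-regulated, the rest down-regulated
    rank_within_class = np.zeros(n_sig, dtype=int)
    for c in range(K):
        members = np.flatnonzero(sig_class == c)
        rank_within_class[members] = np.arange(len(members))
    sig_sign = np.ones(n_sig)
    for i, c in enumerate(sig_class):
        s_c = int((sig_class == c).sum())
        if rank_within_class[i] >= round(up[c] * s_c):
            sig_sign[i] = -1.0
    effect = np.zeros((n, p))
    for g, c, sgn in zip(sig_idx, sig_class, sig_sign):
        effect[label_idx == c, g] = sgn * config.class_effect_size

    z = baseline[None, :] + effect + rng_bio.normal(0.0, config.biological_sd, size=(n, p))

    shift = rng_plat.normal(0.0, config.platform_shift_sd, size=p)
    lo, hi = config.platform_scale_range
    scale = rng_plat.uniform(lo, hi, size=p)

    A = z + rng_na.normal(0.0, config.noise_sd, size=(n, p))
    zc = z - config.platform_b_centering * baseline[None, :]
    B = shift[None, :] + scale[None, :] * zc + config.nonlinearity_strength * _saturating(zc)
    B = B + rng_nb.normal(0.0, config.noise_sd, size=(n, p))

    truth = {
        "config": asdict(config),
        "signature_gene_ids": {
            class_names[c]: [gene_ids[g] for g, cc in zip(sig_idx, sig_class) if cc == c] for c in range(K)
        },
        "signature_effects": {
            gene_ids[g]: {"class": class_names[c], "effect": float(sgn * config.class_effect_size)}
            for g, c, sgn in zip(sig_idx, sig_class, sig_sign)
        },
        "platform_shift": dict(zip(gene_ids, shift.tolist())),
        "platform_scale": dict(zip(gene_ids, scale.tolist())),
    }
    return PairedCohort(
        ExpressionMatrix(A, sample_ids, gene_ids),
        ExpressionMatrix(B, sample_ids, gene_ids),
        labels,
        truth,
    )


def split_cohort(cohort: PairedCohort, train_fraction: float, seed: int = 0) -> tuple[PairedCohort, PairedCohort]:
    """Stratified-by-label sample split applied identically to both platforms."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    labels = np.asarray(cohort.labels.labels, dtype=object)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in cohort.labels.classes:
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        n_train = int(round(train_fraction * len(members)))
        if n_train == 0 or n_train == len(members):
            raise ValueError(f"class '{cls}' would be emptied by the split")
        train_idx.extend(members[:n_train].tolist())
        test_idx.extend(members[n_train:].tolist())
    return cohort.subset(sorted(train_idx)), cohort.subset(sorted(test_idx))
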