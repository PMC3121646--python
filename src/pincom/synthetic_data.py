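"""Synthetic multi-class benchmarks with an exact Bayes-posterior oracle.

The generator emulates the statistical setting the precision-index method
targets: a gene-function-style problem with ~21 unevenly sized classes
(8–50 instances each, ~367 in total), ~60 numeric features, and classes of
heterogeneous separability so that different base learners dominate
different classes.  Classes are spherical Gaussians with a shared variance;
the shared spherical covariance keeps the Bayes posterior closed-form, so a
perfectly calibrated reference classifier is available for calibration
tests.

:func:`make_expert_models` builds complementary pseudo-classifiers — each an
exact Bayes rule on its specialty classes but operating under perturbed
class means elsewhere — to engineer the regime where no single model is
best and combining on the PIN scale must win.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .datatypes import LabeledDataset, PosteriorMatrix

# 21 classes, sizes 8..50 summing to 367 (the emulated study design)
DEFAULT_SIZES = (8, 8, 9, 10, 10, 11, 12, 12, 13, 14, 15, 16, 17, 18, 19,
                 20, 21, 22, 25, 37, 50)
DEFAULT_D = 60


class ConfigError(ValueError):
    pass


@dataclass
class MixtureConfig:
    """Gaussian-mixture study design.

    ``separability`` scales each class's mean norm: classes with small
    multipliers sit close to the origin (hard), large ones far (easy),
    which is what makes different learners dominate different classes.
    """

    sizes: tuple[int, ...] = DEFAULT_SIZES
    d: int = DEFAULT_D
    sigma: float = 1.0
    base_separation: float = 2.5
    separability: tuple[float, ...] | None = None  # default: linspace(0.5, 2)
    seed: int = 0
    means: np.ndarray | None = None  # (C, d); derived from seed if omitted

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ConfigError("all class sizes must be >= 1")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        C = len(self.sizes)
        if self.separability is None:
            self.separability = tuple(np.linspace(0.5, 2.0, C))
        if len(self.separability) != C:
            raise ConfigError("separability must have one multiplier per class")
        if self.means is None:
            rng = np.random.default_rng(self.seed + 7919)  # mean layout stream
            raw = rng.standard_normal((C, self.d))
            raw /= np.linalg.norm(raw, axis=1, keepdims=True)
            self.means = (
                raw * self.base_separation * np.asarray(self.separability)[:, None]
            )
        else:
            self.means = np.asarray(self.means, dtype=float)
            if self.means.shape != (C, self.d):
                raise ConfigError(
                    f"means shape {self.means.shape} != ({C}, {self.d})"
                )

    @property
    def C(self) -> int:
        return len(self.sizes)

    @property
    def class_vocab(self) -> list[str]:
        return [f"C{k:02d}" for k in range(self.C)]

    @property
    def n(self) -> int:
        return int(sum(self.sizes))


def _draw(cfg: MixtureConfig, sizes: Sequence[int], rng, tag: str) -> LabeledDataset:
    X, labels, ids = [], [], []
    vocab = cfg.class_vocab
    i = 0
    for k, n_k in enumerate(sizes):
        X.append(rng.normal(cfg.means[k], cfg.sigma, size=(n_k, cfg.d)))
        labels.extend([vocab[k]] * n_k)
        ids.extend([f"{tag}{i + j}" for j in range(n_k)])
        i += n_k
    return LabeledDataset(
        instance_ids=ids,
        features=np.vstack(X),
        labels=np.array(labels, dtype=object),
        class_vocab=list(vocab),
    )


def generate(
    cfg: MixtureConfig, test_sizes: Sequence[int] | None = None
) -> LabeledDataset | tuple[LabeledDataset, LabeledDataset]:
    """Draw the labeled training set (and optionally a disjoint test set).

    Sampling is per class with deterministic counts — the empirical class
    frequencies equal ``cfg.sizes`` exactly.  Pure function of ``cfg``.
    """
    rng = np.random.default_rng(cfg.seed)
    train = _draw(cfg, cfg.sizes, rng, "g")
    if test_sizes is None:
        return train
    if len(test_sizes) != cfg.C:
        raise ConfigError("test_sizes must have one count per class")
    test = _draw(cfg, test_sizes, rng, "t")
    return train, test


def _log_posterior(
    X: np.ndarray, means: np.ndarray, sigma: float, sizes: Sequence[int]
) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    # shared spherical covariance: log N(x; mu_k, s^2 I) up to a constant
    d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    logp = -d2 / (2.0 * sigma**2) + np.log(np.asarray(sizes, dtype=float))
    return logp - logsumexp(logp, axis=1, keepdims=True)


def bayes_posterior(cfg: MixtureConfig, x: np.ndarray) -> np.ndarray:
    """Exact class posterior p(k | x) under the generating mixture.

    Priors are proportional to the class sizes.  Accepts one point (returns
    a length-C vector) or a matrix of points (returns rows).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    post = np.exp(_log_posterior(x, cfg.means, cfg.sigma, cfg.sizes))
    return post[0] if single else post


def bayes_posterior_matrix(
    cfg: MixtureConfig, X: np.ndarray, instance_ids: Sequence[str] | None = None
) -> PosteriorMatrix:
    """The Bayes oracle packaged as a perfectly calibrated classifier output."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(instance_ids) if instance_ids is not None else [f"x{i}" for i in range(len(X))]
    return PosteriorMatrix("bayes", ids, bayes_posterior(cfg, X), cfg.class_vocab)


@dataclass
class ExpertModel:
    """Pseudo-classifier: exact Bayes posterior wherever the Bayes-optimal
    class lies in its specialty, a noise-degraded posterior elsewhere.

    Off-specialty rows are a ``noise``-weighted blend of the true posterior
    with a random distribution, so their predictions drift toward chance
    and their confidences shrink while specialty rows stay perfectly
    calibrated — engineered complementarity.  ``noise = 0`` reduces exactly
    to the Bayes oracle.
    """

    model_id: str
    cfg: MixtureConfig
    specialty: frozenset[str]
    noise: float
    noise_seed: int

    def predict_proba(
        self, X: np.ndarray, instance_ids: Sequence[str] | None = None
    ) -> PosteriorMatrix:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        probs = np.exp(_log_posterior(X, self.cfg.means, self.cfg.sigma, self.cfg.sizes))
        if self.noise > 0:
            vocab = self.cfg.class_vocab
            spec_cols = [j for j, c in enumerate(vocab) if c in self.specialty]
            off = ~np.isin(np.argmax(probs, axis=1), spec_cols)
            rng = np.random.default_rng(self.noise_seed)
            rand = rng.exponential(size=probs.shape)  # flat Dirichlet rows
            rand /= rand.sum(axis=1, keepdims=True)
            w = min(self.noise, 1.0)
            probs[off] = (1.0 - w) * probs[off] + w * rand[off]
            probs /= probs.sum(axis=1, keepdims=True)
        ids = (
            list(instance_ids)
            if instance_ids is not None
            else [f"x{i}" for i in range(len(X))]
        )
        return PosteriorMatrix(self.model_id, ids, probs, self.cfg.class_vocab)


def make_expert_models(
    cfg: MixtureConfig,
    specialties: Sequence[Sequence[str]],
    noise: float = 1.0,
) -> list[ExpertModel]:
    """Build L complementary pseudo-models from a partition of the classes.

    ``specialties`` must partition the class vocabulary.  ``noise`` in
    [0, 1] is the blend weight toward a random distribution on
    off-specialty rows (1 = pure noise there).  Each model draws its noise
    from a dedicated stream derived from ``cfg.seed``, so outputs are pure
    functions of the configuration.
    """
    vocab = cfg.class_vocab
    flat = [c for spec in specialties for c in spec]
    if sorted(flat) != sorted(vocab):
        raise ConfigError(
            "specialties must partition the class vocabulary exactly"
        )
    return [
        ExpertModel(
            model_id=f"expert{m}",
            cfg=cfg,
            specialty=frozenset(spec),
            noise=noise,
            noise_seed=int(
                np.random.SeedSequence([cfg.seed, 104729, m]).generate_state(1)[0]
                % (2**31)
            ),
        )
        for m, spec in enumerate(specialties)
    ]


def small_config(seed: int = 0, n_per_class: int = 30, C: int = 6, d: int = 8,
                 sigma: float = 1.0, base_separation: float = 2.5) -> MixtureConfig:
    """Compact design for fast protocol runs and examples."""
    return MixtureConfig(
        sizes=tuple([n_per_class] * C), d=d, sigma=sigma,
        base_separation=base_separation, seed=seed,
    )
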