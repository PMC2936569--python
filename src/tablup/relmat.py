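"""Marker-derived relationship matrices: realized (G) and trait-specific (TA).

The element for an individual pair is built in three steps:

1. per-locus full identity-by-state: all four cross-individual allele
   comparisons are averaged, so the score lives in {0, .25, .5, .75, 1}
   and no phasing is required;
2. a weighted average over loci, S_ij = sum_k w_k S_ijk / sum_k w_k,
   where the weights carry the trait information (uniform -> G,
   RRBLUP expected variances 2p(1-p)g^2 -> TAP, BayesB posterior
   variances -> TAB);
3. a correction for the population mean IBS (Wright's F-statistics
   form), f_ij = (S_ij - S_bar) / (1 - S_bar), and doubling, since
   relatedness is twice the IBD probability.

The ad-hoc variants skip step 3, use |g_hat| weights and force a unit
diagonal (no-inbreeding assumption).

For biallelic loci coded as allele-2 counts x in {0,1,2} the per-locus
score has the closed form S = (1 + c_i c_j) / 2 with c = x - 1, so the
whole weighted matrix reduces to a single rank-N product -- that is
what :func:`weighted_ibs` computes; :func:`locus_similarity` is the
literal four-comparison definition, kept as the independent form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightScheme",
    "RelationshipMatrix",
    "locus_similarity",
    "weighted_ibs",
    "correct_mean_ibs",
    "build_relationship",
    "scheme_g",
    "scheme_tap",
    "scheme_tab",
    "scheme_adhoc",
]


@dataclass
class WeightScheme:
    """Per-marker weights plus the construction flags of Table-1 schemes."""

    name: str
    weights: np.ndarray | None = None  # None -> uniform
    mean_correction: bool = True
    unit_diagonal: bool = False

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1:
                raise ValueError("weights must be a vector")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            if not np.any(w > 0):
                raise ValueError("at least one weight must be positive")
            self.weights = w


def scheme_g() -> WeightScheme:
    """Unweighted realized relationship matrix (GBLUP)."""
    return WeightScheme("G", None, mean_correction=True)


def scheme_tap(marker_effects) -> WeightScheme:
    """TA with RRBLUP expected-variance weights 2p(1-p)g_hat^2."""
    return WeightScheme("TAP", np.asarray(marker_effects.variance_weights, float))


def scheme_tab(marker_effects) -> WeightScheme:
    """TA with BayesB posterior marker-variance weights."""
    return WeightScheme("TAB", np.asarray(marker_effects.variance_weights, float))


def scheme_adhoc(marker_effects) -> WeightScheme:
    """Ad-hoc variant: |g_hat| weights, raw IBS, unit diagonal."""
    tag = "TAB*" if marker_effects.method == "bayesb" else "TAP*"
    return WeightScheme(
        tag,
        np.abs(np.asarray(marker_effects.g_hat, float)),
        mean_correction=False,
        unit_diagonal=True,
    )


@dataclass
class RelationshipMatrix:
    """A symmetric individual x individual relationship matrix."""

    values: np.ndarray
    scheme: str
    weights: np.ndarray
    mean_ibs: float | None = None  # S_bar used by the correction
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def locus_similarity(geno_i, geno_j) -> float:
    """Full IBS score between two unordered allele pairs.

    Averages the four cross-individual allele identity indicators, so
    e.g. (1,2) vs (1,2) -> 0.5 and heterozygote vs anything -> 0.5.
    """
    (a, b), (c, d) = geno_i, geno_j
    return (int(a == c) + int(a == d) + int(b == c) + int(b == d)) / 4.0


def weighted_ibs(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-average IBS matrix S over all loci.

    ``genotypes`` counts allele 2 per individual and locus (0/1/2).
    Weighted by ``weights`` and normalised by their sum, so sparse
    weight vectors keep S on the [0, 1] scale.
    """
    X = np.asarray(genotypes)
    if X.ndim != 2:
        raise ValueError("genotypes must be 2-D (individuals x markers)")
    if X.size and (X.min() < 0 or X.max() > 2):
        raise ValueError("genotypes must count allele 2 (0, 1 or 2)")
    w = np.asarray(weights, dtype=float)
    if w.shape != (X.shape[1],):
        raise ValueError("weights length must equal the marker count")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("weights sum to zero")
    # S_ij = 0.5 + sum_k w_k c_ik c_jk / (2 sum_k w_k), c = x - 1
    C = (X.astype(np.float32) - 1.0) * np.sqrt(w / (2.0 * sw), dtype=np.float32)
    S = 0.5 + (C @ C.T).astype(np.float64)
    return 0.5 * (S + S.T)


def correct_mean_ibs(S: np.ndarray) -> np.ndarray:
    """Rescale similarities to relatedness via the mean-IBS correction.

    f_ij = (S_ij - S_bar) / (1 - S_bar) with S_bar the mean of S over
    off-diagonal pairs; identical populations (S_bar = 1) are rejected
    as degenerate.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    s_bar = (S.sum() - np.trace(S)) / (n * (n - 1))
    if s_bar >= 1.0 - 1e-12:
        raise ValueError("population average IBS is 1; all individuals identical")
    return (S - s_bar) / (1.0 - s_bar)


def build_relationship(
    genotypes: np.ndarray,
    scheme: WeightScheme,
    jitter: float = 0.0,
    ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Construct the relationship matrix for one weighting scheme.

    Corrected schemes (G, TAP, TAB) return twice the mean-corrected
    weighted IBS, diagonal included (self-similarity runs through the
    same pipeline, so homozygosity excess shows up on the diagonal).
    Ad-hoc schemes return the raw weighted IBS with a unit diagonal.
    ``jitter`` adds a ridge to the diagonal for panels so small that
    the matrix becomes singular; it is off by default.
    """
    X = np.asarray(genotypes)
    w = (
        np.ones(X.shape[1])
        if scheme.weights is None
        else np.asarray(scheme.weights, float)
    )
    S = weighted_ibs(X, w)
    s_bar: float | None = None
    if scheme.mean_correction:
        n = S.shape[0]
        s_bar = float((S.sum() - np.trace(S)) / (n * (n - 1)))
        R = 2.0 * correct_mean_ibs(S)
    else:
        R = S
    if scheme.unit_diagonal:
        np.fill_diagonal(R, 1.0)
    if jitter:
        R = R + jitter * np.eye(R.shape[0])
    R = 0.5 * (R + R.T)
    return RelationshipMatrix(R, scheme.name, w, mean_ibs=s_bar, ids=ids)
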