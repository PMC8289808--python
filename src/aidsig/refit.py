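"""Refitting of fixed reference mutational signatures to 96-channel catalogs.

A catalog is expressed as a non-negative combination of known
single-base-substitution (SBS) signatures (e.g. COSMIC v3 SBS1-30 plus the
AID-associated SBS84/SBS85) by non-negative least squares (NNLS) on raw
mutation counts:

    minimise || catalog - S @ w ||_2   subject to  w >= 0

where S is the 96 x K signature matrix.  Relative contributions are the
normalised weights, and refit quality is the cosine similarity between the
observed catalog and the reconstructed profile S @ w.  This is refitting,
not de novo extraction: the signature basis is fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import CHANNELS, N_CHANNELS, cosine_similarity

#: AID-associated signatures per the COSMIC v3 nomenclature
AID_SIGNATURES: tuple[str, ...] = ("SBS9", "SBS84", "SBS85")


@dataclass(slots=True)
class SignatureSet:
    """Named 96-row probability columns used as the fixed refitting basis."""

    names: list[str]
    matrix: np.ndarray  # (96, K), columns sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_CHANNELS, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match 96 x {len(self.names)}"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown signature names {missing}")
        idx = [self.names.index(n) for n in names]
        return SignatureSet(list(names), self.matrix[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS), columns=self.names)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="Type")


@dataclass(slots=True)
class RefitResult:
    """NNLS refit of one catalog against a fixed signature set."""

    signature_names: list[str]
    weights: np.ndarray          # absolute, mutation-count scale
    contributions: np.ndarray    # weights / sum(weights), sums to 1
    reconstructed: np.ndarray    # matrix @ weights
    cosine: float
    n_mutations: int

    def contribution_of(self, name: str) -> float:
        return float(self.contributions[self.signature_names.index(name)])

    def to_series(self) -> pd.Series:
        s = pd.Series(self.contributions, index=self.signature_names)
        s["cosine"] = self.cosine
        s["n_mutations"] = self.n_mutations
        return s


@dataclass(slots=True)
class AidSignatureAggregate:
    """Summed relative contribution of the AID-associated signatures."""

    aid_contribution: float
    member_signatures: tuple[str, ...]


def load_signatures(path: str | Path, subset: Sequence[str] | None = None) -> SignatureSet:
    """Load a tab-separated signature matrix (COSMIC v3 layout).

    First column holds the 96 trinucleotide channel labels; remaining
    columns are named signatures.  Rows are reordered to the canonical
    channel order.  Columns are required to sum to 1 within 1e-3 (public
    releases are rounded) and are renormalised to exact unit sum.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CHANNELS if c not in df.index]
    if missing:
        raise ValueError(f"{path}: missing channel rows, e.g. {missing[:3]}")
    if len(df.index) != N_CHANNELS:
        extra = [c for c in df.index if c not in set(CHANNELS)]
        raise ValueError(f"{path}: unexpected rows {extra[:3]}")
    df = df.loc[list(CHANNELS)]
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric signature cell: {exc}") from exc
    sums = matrix.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        bad = [df.columns[i] for i in np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-3))]
        raise ValueError(f"{path}: signature columns do not sum to ~1: {bad}")
    matrix = matrix / sums
    sigs = SignatureSet(list(df.columns), matrix)
    if subset is not None:
        sigs = sigs.subset(subset)
    return sigs


def refit(catalog: np.ndarray, sigs: SignatureSet) -> RefitResult:
    """Non-negative least-squares refit of one 96-channel catalog.

    Deterministic for fixed input (NNLS has a unique active set for
    generic problems and scipy's solver is deterministic).
    """
    catalog = np.asarray(catalog, dtype=float)
    if catalog.shape != (N_CHANNELS,):
        raise ValueError(f"catalog must be a 96-vector, got shape {catalog.shape}")
    if (catalog < 0).any():
        raise ValueError("catalog counts must be non-negative")
    total = catalog.sum()
    if total == 0:
        raise ValueError("cannot refit an all-zero catalog")
    weights, _ = nnls(sigs.matrix, catalog)
    wsum = weights.sum()
    contributions = weights / wsum if wsum > 0 else np.zeros_like(weights)
    reconstructed = sigs.matrix @ weights
    if reconstructed.sum() == 0:
        cosine = 0.0
    else:
        cosine = cosine_similarity(catalog, reconstructed)
    return RefitResult(
        signature_names=list(sigs.names),
        weights=weights,
        contributions=contributions,
        reconstructed=reconstructed,
        cosine=cosine,
        n_mutations=int(round(total)),
    )


def refit_quality(result: RefitResult, catalog: np.ndarray) -> float:
    """Cosine similarity between the observed and reconstructed profile.

    Returns 0.0 (with a warning) when the reconstruction is the zero
    vector, where cosine similarity is undefined.
    """
    if result.reconstructed.sum() == 0:
        import warnings

        warnings.warn("zero reconstructed profile; refit quality reported as 0", stacklevel=2)
        return 0.0
    return cosine_similarity(np.asarray(catalog, dtype=float), result.reconstructed)


def aid_contribution(
    result: RefitResult, members: Sequence[str] = AID_SIGNATURES
) -> AidSignatureAggregate:
    """Aggregate relative contribution over the AID-associated signatures."""
    unknown = [m for m in members if m not in result.signature_names]
    if unknown:
        raise KeyError(f"unknown signature names {unknown}")
    total = sum(result.contribution_of(m) for m in members)
    return AidSignatureAggregate(aid_contribution=float(total), member_signatures=tuple(members))


class SignatureRefitter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: mutation catalogs -> signature contributions.

    Each row of X is an independent 96-channel catalog; ``transform``
    returns the (n_samples, K) matrix of relative contributions from a
    per-row NNLS refit against the fixed ``signatures`` basis.

    Attributes (after ``fit``)
    --------------------------
    results_ : list of :class:`RefitResult`, one per fitted row.
    weights_, contributions_ : (n_samples, K) arrays.
    cosine_similarities_ : per-sample reconstruction quality.
    aid_contributions_ : per-sample summed contribution of ``aid_members``.
    """

    def __init__(
        self,
        signatures: SignatureSet | None = None,
        aid_members: Sequence[str] = AID_SIGNATURES,
    ):
        self.signatures = signatures
        self.aid_members = aid_members

    def _validate(self, X) -> np.ndarray:
        if self.signatures is None:
            raise ValueError("SignatureRefitter requires a SignatureSet")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != N_CHANNELS:
            raise ValueError(f"X must have 96 columns, got {X.shape[1]}")
        return X

    def fit(self, X, y=None) -> "SignatureRefitter":
        X = self._validate(X)
        self.n_features_in_ = N_CHANNELS
        self.results_ = [refit(row, self.signatures) for row in X]
        self.weights_ = np.vstack([r.weights for r in self.results_])
        self.contributions_ = np.vstack([r.contributions for r in self.results_])
        self.cosine_similarities_ = np.array([r.cosine for r in self.results_])
        members = [m for m in self.aid_members if m in self.signatures.names]
        self.aid_contributions_ = np.array(
            [aid_contribution(r, members).aid_contribution if members else 0.0 for r in self.results_]
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "results_")
        X = self._validate(X)
        return np.vstack([refit(row, self.signatures).contributions for row in X])

    def get_feature_names_out(self, input_features=None):
        if self.signatures is None:
            raise ValueError("SignatureRefitter requires a SignatureSet")
        return np.asarray(self.signatures.names, dtype=object)


def refit_frame(catalogs, sigs: SignatureSet) -> pd.DataFrame:
    """Refit a list of :class:`~aidsig.catalog.Catalog96`; tidy output table.

    One row per sample with relative contributions per signature plus
    ``cosine`` and ``n_mutations`` columns (the refit TSV layout).
    """
    rows = {}
    for cat in catalogs:
        if cat.total == 0:
            s = pd.Series(np.nan, index=list(sigs.names) + ["cosine"])
            s["n_mutations"] = 0
            rows[cat.sample_id] = s
        else:
            rows[cat.sample_id] = refit(cat.counts, sigs).to_series()
    df = pd.DataFrame(rows).T
    df.index.name = "sample"
    return df
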