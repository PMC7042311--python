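"""Trinucleotide mutational-signature decomposition and stratification.

Single-base substitutions are classified into 96 trinucleotide channels
(six pyrimidine-centred substitution types x 16 flanking contexts). A
sample's channel counts are decomposed against a reference signature
matrix by non-negative least squares; signatures receiving non-zero
exposure become the sample's candidate set. Each mutation is then
assigned to the candidate signature under which its channel is most
likely, provided that likelihood is at least twice the likelihood under
every other candidate — otherwise it goes to "Other". Distance histograms
can then be built per signature stratum, enabling signature-specific
mutation-rate inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceHistogram, SampleProfile, build_histogram

__all__ = [
    "CHANNELS_96",
    "SignatureMatrix",
    "MutationAssignment",
    "fit_exposures",
    "assign_mutation",
    "stratified_histograms",
    "toy_signature_matrix",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: canonical 96 trinucleotide channels, e.g. "A[C>A]A", in COSMIC order
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)


class SignatureMatrix:
    """Reference signatures: 96 channel probabilities per named signature."""

    def __init__(self, data: pd.DataFrame) -> None:
        if list(data.index) != list(CHANNELS_96):
            data = data.reindex(CHANNELS_96)
            if data.isna().any().any():
                raise ValueError("signature matrix must cover all 96 channels")
        vals = data.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")
        self.data = data.astype(float)
        self.data.index.name = "channel"

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def subset(self, names) -> "SignatureMatrix":
        return SignatureMatrix(self.data[list(names)])

    def channel_prob(self, channel: str, name: str) -> float:
        if channel not in self.data.index:
            raise KeyError(f"unknown trinucleotide channel {channel!r}")
        return float(self.data.loc[channel, name])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class MutationAssignment:
    """Signature call for one mutation under the two-fold likelihood rule."""

    mutation: object
    signature: str  # a signature name or "Other"
    likelihoods: dict


def fit_exposures(channel_counts, sigs: SignatureMatrix) -> pd.Series:
    """Non-negative least-squares signature exposures for one sample.

    Returns exposures (mutation counts attributed to each signature);
    signatures with exposure above a small tolerance form the candidate
    set for per-mutation assignment.
    """
    from scipy.optimize import nnls

    counts = np.asarray(channel_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"expected a 96-vector of channel counts, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("channel counts must be non-negative")
    if counts.sum() == 0:
        return pd.Series(0.0, index=sigs.names)
    coef, _ = nnls(sigs.data.to_numpy(), counts)
    return pd.Series(coef, index=sigs.names)


def candidate_signatures(exposures: pd.Series, tol: float = 1e-8) -> list[str]:
    """Signatures carrying non-zero exposure."""
    return [name for name, e in exposures.items() if e > tol]


def assign_mutation(
    channel: str,
    candidates: SignatureMatrix,
    mutation=None,
    fold: float = 2.0,
) -> MutationAssignment:
    """Assign one mutation's channel to a candidate signature.

    The winning signature must make the channel at least ``fold`` times
    as likely as every other candidate; ties or weaker contrasts yield
    "Other". A single candidate is always assigned (when it gives the
    channel any support).
    """
    if not candidates.names:
        raise ValueError("candidate set is empty")
    liks = {name: candidates.channel_prob(channel, name) for name in candidates.names}
    order = sorted(liks.items(), key=lambda kv: kv[1], reverse=True)
    top_name, top_lik = order[0]
    if top_lik <= 0:
        return MutationAssignment(mutation, "Other", liks)
    if len(order) == 1 or top_lik >= fold * order[1][1]:
        return MutationAssignment(mutation, top_name, liks)
    return MutationAssignment(mutation, "Other", liks)


def stratified_histograms(
    assignments: dict,
    profiles,
    **histogram_kwargs,
) -> dict[str, DistanceHistogram]:
    """Per-signature mutational-distance histograms.

    ``assignments`` maps every mutation identifier appearing in the
    profiles to a signature name (or "Other"). Each profile is split into
    per-stratum sub-profiles and the distance histogram is built within
    each stratum; because the strata partition each genotype, the
    per-pair stratum distances sum exactly to the unstratified ones.
    """
    profiles = list(profiles)
    strata: set[str] = set()
    for p in profiles:
        for mut in p.mutations:
            if mut not in assignments:
                raise KeyError(f"mutation {mut!r} has no signature assignment")
            strata.add(assignments[mut])
    out: dict[str, DistanceHistogram] = {}
    for stratum in sorted(strata):
        sub = [
            SampleProfile(
                p.sample_id,
                frozenset(m for m in p.mutations if assignments[m] == stratum),
            )
            for p in profiles
        ]
        out[stratum] = build_histogram(sub, **histogram_kwargs)
    return out


def toy_signature_matrix(n_signatures: int = 6, seed: int = 20) -> SignatureMatrix:
    """Synthetic reference matrix for tests and examples.

    Deterministic stand-in for an external signature catalogue (none is
    shipped): each synthetic signature concentrates 80% of its mass on a
    distinct block of 16 channels (one substitution type) with a flat 20%
    background, giving well-separated likelihood contrasts.
    """
    if not (1 <= n_signatures <= 6):
        raise ValueError("toy matrix supports 1..6 signatures")
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_signatures):
        block = np.full(96, 0.2 / 96)
        weights = rng.dirichlet(np.ones(16))
        block[16 * k : 16 * (k + 1)] += 0.8 * weights
        cols[f"SynthSig{k + 1}"] = block / block.sum()
    return SignatureMatrix(pd.DataFrame(cols, index=list(CHANNELS_96)))
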