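"""Distance-threshold authentication over stored EEG fingerprints.

The system is the tuple (A, S, f, l): A are raw EEG samples, f is the
fingerprinting function, S the stored fingerprints, and l accepts a claim
iff distance(stored, f(fresh sample)) <= threshold.  Only fingerprints are
ever stored — never raw signals or model inputs.

Note on the cosine metric: the similarity A.B/(|A||B|) is large for similar
vectors, which would invert the accept-if-small rule, so the implemented
cosine *distance* is 1 - similarity.  Small distance always means similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DuplicateIdentityError,
    ShapeError,
    StaleModelError,
    UndefinedDistanceError,
    UnknownIdentityError,
)
from .fingerprint_model import (
    FingerprintFunction,
    FingerprintVector,
    fingerprint_sample,
)
from .preprocess import WindowParams
from .signal_io import (
    EegRecording,
    load_fingerprint_store,
    save_fingerprint_store,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DISTANCES",
    "distance",
    "AuthPolicy",
    "AuthDecision",
    "EnrollmentStore",
    "enroll",
    "verify",
]


def _euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))

def _manhattan(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum())

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedDistanceError("cosine distance undefined for zero vectors")
    return float(1.0 - (a @ b) / (na * nb))

DISTANCES = {
    "euclidean": _euclidean,
    "manhattan": _manhattan,
    "cosine": _cosine,
}


def distance(a, b, name: str = "cosine") -> float:
    """Distance between two fingerprint vectors; small means similar."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"vector lengths differ: {a.size} vs {b.size}")
    try:
        fn = DISTANCES[name.lower()]
    except KeyError:
        raise UndefinedDistanceError(
            f"unknown distance {name!r}; choose from {sorted(DISTANCES)}"
        ) from None
    return fn(a, b)


@dataclass(frozen=True)
class AuthPolicy:
    """Distance measure plus acceptance threshold (accept iff <=)."""

    distance_name: str = "cosine"
    threshold: float = 0.275

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ShapeError("threshold must be non-negative")
        if self.distance_name.lower() not in DISTANCES:
            raise UndefinedDistanceError(
                f"unknown distance {self.distance_name!r}"
            )


@dataclass(frozen=True)
class AuthDecision:
    accepted: bool
    measured_distance: float
    policy: AuthPolicy
    reason: str = "distance"  # "distance" | "unknown-identity"


class EnrollmentStore:
    """Identity -> fingerprint table; the set S of the authentication model.

    Holds only fixed-length fingerprint vectors and enrollment metadata
    (channel list, window-parameter echo, model version) — never raw signal
    arrays or model inputs.
    """

    def __init__(self, model_version: str):
        self.model_version = model_version
        self._entries: dict[str, dict] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, identity: str) -> bool:
        return identity in self._entries

    def identities(self) -> list[str]:
        return sorted(self._entries)

    def add(self, identity: str, fingerprint: FingerprintVector,
            channels, params: WindowParams, overwrite: bool = False) -> None:
        if identity in self._entries and not overwrite:
            raise DuplicateIdentityError(
                f"identity {identity!r} is already enrolled"
            )
        if fingerprint.model_version != self.model_version:
            raise StaleModelError(
                f"fingerprint model {fingerprint.model_version} != "
                f"store model {self.model_version}"
            )
        self._entries[identity] = {
            "fingerprint": fingerprint.values.tolist(),
            "channels": list(channels),
            "params": params.to_dict(),
        }

    def get(self, identity: str) -> FingerprintVector:
        try:
            entry = self._entries[identity]
        except KeyError:
            raise UnknownIdentityError(f"identity {identity!r} not enrolled") from None
        return FingerprintVector(
            values=np.asarray(entry["fingerprint"]),
            model_version=self.model_version,
        )

    def save(self, path) -> None:
        save_fingerprint_store(path, self.model_version, self._entries)

    @classmethod
    def load(cls, path) -> "EnrollmentStore":
        model_version, entries = load_fingerprint_store(path)
        store = cls(model_version)
        store._entries = entries
        return store


def enroll(
    store: EnrollmentStore,
    identity: str,
    recording: EegRecording,
    f: FingerprintFunction,
    channels,
    params: WindowParams,
    overwrite: bool = False,
    orthogonalize_flag: bool = True,
) -> EnrollmentStore:
    """Fingerprint a recording and store it under ``identity``.

    The raw recording is not retained anywhere in the store.
    """
    fingerprint = fingerprint_sample(
        f, recording, channels, params, orthogonalize_flag=orthogonalize_flag
    )
    store.add(identity, fingerprint, channels, params, overwrite=overwrite)
    logger.info("enrolled %s (fingerprint length %d)", identity, len(fingerprint))
    return store


def verify(
    store: EnrollmentStore,
    claimed_identity: str,
    recording: EegRecording,
    f: FingerprintFunction,
    policy: AuthPolicy,
    channels,
    params: WindowParams,
    orthogonalize_flag: bool = True,
) -> AuthDecision:
    """Authenticate a claim: recompute the fingerprint server-side from the
    raw sample and accept iff its distance to the stored one is <= threshold.

    Unknown identities are rejected with ``reason="unknown-identity"``,
    distinct from a distance rejection.
    """
    if claimed_identity not in store:
        logger.info("claim for unknown identity %r rejected", claimed_identity)
        return AuthDecision(
            accepted=False,
            measured_distance=float("inf"),
            policy=policy,
            reason="unknown-identity",
        )
    if f.model_version != store.model_version:
        raise StaleModelError(
            f"fingerprint function model {f.model_version} does not match "
            f"store model {store.model_version}"
        )
    stored = store.get(claimed_identity)
    fresh = fingerprint_sample(
        f, recording, channels, params, orthogonalize_flag=orthogonalize_flag
    )
    d = distance(stored.values, fresh.values, policy.distance_name)
    accepted = d <= policy.threshold
    logger.info(
        "verify claim=%s distance=%.6f threshold=%.6f -> %s",
        claimed_identity, d, policy.threshold,
        "ACCEPT" if accepted else "REJECT",
    )
    return AuthDecision(accepted=accepted, measured_distance=d, policy=policy)
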