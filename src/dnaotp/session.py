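"""Session management and the end-to-end encrypt/decrypt pipeline.

A :class:`CipherSession` bundles every secret of one encryption session:

* security parameters (key0 and the two logistic pairs) — drive the data
  cipher and travel encrypted as C0;
* confounding parameters (key1, key2, Pk) — drive the parameter cipher and
  travel encrypted as C1;
* data-cipher settings (Arnold iterations, recorded plaintext bit length);
* the channel secret (adapter + ordered index list) shared out-of-band.

The session serializes to a flat, versioned JSON document.  No derived
state is stored: the keystream is always regenerated from the logistic
parameters.  All randomness flows through one generator seeded from the
session seed, so every "randomly selected/added" step is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from datetime import datetime, timezone

import numpy as np

from . import chaos, datacipher, library, params
from .chaos import DEFAULT_BURN_IN, LogisticParams
from .datacipher import DataCipherConfig
from .errors import ParameterError
from .library import ChannelSecret
from .params import ConfoundingParams, SecurityParams

logger = logging.getLogger("dnaotp")

SCHEMA_VERSION = 1


def _digest(data) -> str:
    if isinstance(data, str):
        data = data.encode()
    elif isinstance(data, np.ndarray):
        data = data.tobytes()
    return hashlib.sha256(data).hexdigest()[:12]


@dataclass
class CipherSession:
    """All parameters of one encryption session."""

    security: SecurityParams
    confounding: ConfoundingParams
    data: DataCipherConfig
    channel: ChannelSecret | None = None
    burn_in: int = DEFAULT_BURN_IN
    created: str = ""
    seed: int | None = None

    def __post_init__(self):
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")
        if self.data.key0 != self.security.key0:
            raise ParameterError("data-cipher key0 must equal the security key0")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": SCHEMA_VERSION,
            "created": self.created,
            "seed": self.seed,
            "burn_in": self.burn_in,
            "security": {
                "key0": self.security.key0,
                "mu0": self.security.mu0,
                "g0": self.security.g0,
                "mu1": self.security.mu1,
                "g1": self.security.g1,
            },
            "confounding": {
                "key1": self.confounding.key1,
                "key2": self.confounding.key2,
                "pk": self.confounding.pk,
            },
            "data": {
                "arnold_iterations": self.data.arnold_iterations,
                "arnold_m": self.data.arnold_m,
                "arnold_n": self.data.arnold_n,
                "bit_length": self.data.bit_length,
            },
            "channel": None
            if self.channel is None
            else {
                "adapter": self.channel.adapter,
                "index_list": list(self.channel.index_list),
                "payload_pad": self.channel.payload_pad,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "CipherSession":
        if doc.get("version") != SCHEMA_VERSION:
            raise ParameterError(f"unsupported session schema version {doc.get('version')!r}")
        sec = SecurityParams(**doc["security"])
        con = ConfoundingParams(**doc["confounding"])
        data = DataCipherConfig(key0=sec.key0, **doc["data"])
        ch = doc.get("channel")
        channel = (
            None
            if ch is None
            else ChannelSecret(ch["adapter"], tuple(ch["index_list"]), ch["payload_pad"])
        )
        return cls(
            security=sec,
            confounding=con,
            data=data,
            channel=channel,
            burn_in=doc.get("burn_in", DEFAULT_BURN_IN),
            created=doc.get("created", ""),
            seed=doc.get("seed"),
        )

    @classmethod
    def from_json(cls, text: str) -> "CipherSession":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "CipherSession":
        with open(path) as fh:
            return cls.from_json(fh.read())

    # -- derived objects ----------------------------------------------------

    def logistic_pairs(self) -> tuple[LogisticParams, LogisticParams]:
        s = self.security
        return (
            LogisticParams(float(s.mu0), float(s.g0)),
            LogisticParams(float(s.mu1), float(s.g1)),
        )

    def keystream(self, n_bits: int) -> chaos.KeyStream:
        p0, p1 = self.logistic_pairs()
        return chaos.keystream(p0, p1, n_bits, self.burn_in)


def new_session(seed: int, arnold_iterations: int = 1) -> CipherSession:
    """Draw all session parameters uniformly from their domains, deterministically."""
    rng = np.random.default_rng(seed)
    key0, key1, key2 = (int(v) for v in rng.integers(1, 25, size=3))
    pk = int(rng.integers(0, 13))
    mu0, mu1 = (f"{v:.6f}" for v in rng.uniform(3.569947, 3.999999, size=2))
    g0, g1 = (f"{v:.6f}" for v in rng.uniform(1e-6, 1 - 1e-6, size=2))
    sec = SecurityParams(key0, mu0, g0, mu1, g1)
    con = ConfoundingParams(key1, key2, pk)
    cfg = DataCipherConfig(key0=key0, arnold_iterations=arnold_iterations)
    return CipherSession(security=sec, confounding=con, data=cfg, seed=seed)


@dataclass(frozen=True)
class EncryptedMessage:
    """The three public artifacts of one session."""

    c0: str
    c1: str
    mixture_fasta: str


def encrypt_message(
    plaintext: str,
    session: CipherSession,
    copies: int = 1,
    rng: np.random.Generator | None = None,
) -> EncryptedMessage:
    """Run the full pipeline: parameter cipher + data cipher + DNA library.

    Updates ``session`` in place with the channel secret and the recorded
    plaintext bit length (both needed by the receiver).
    """
    if rng is None:
        if session.seed is None:
            raise ParameterError("session has no seed; pass an rng explicitly")
        rng = np.random.default_rng(session.seed)
    c0 = params.confuse_security(session.security, session.confounding, rng)
    c1 = params.encrypt_confounding(session.confounding, rng)
    logger.debug("C0 digest=%s C1 digest=%s", _digest(c0), _digest(c1))

    n_bits = datacipher.required_keystream_bits(len(plaintext.encode("ascii")) * 8)
    key = session.keystream(n_bits)
    logger.debug("keystream n=%d digest=%s", n_bits, _digest(key.bits))
    c_dna, cfg = datacipher.encrypt_data(plaintext, key, session.data)
    session.data = cfg
    logger.debug("C_DNA len=%d digest=%s", len(c_dna), _digest(c_dna))

    payloads, pad = library.fragment(c_dna)
    secret = library.make_secret(len(payloads), rng, payload_pad=pad)
    records = library.assemble_library(payloads, secret)
    session.channel = secret
    fasta = library.synthesize_mixture(records, rng, copies=copies)
    logger.debug("library n=%d mixture digest=%s", len(records), _digest(fasta))
    return EncryptedMessage(c0=c0, c1=c1, mixture_fasta=fasta)


def decrypt_message(
    c0: str,
    c1: str,
    mixture_fasta: str,
    session: CipherSession,
) -> str:
    """Invert the pipeline given the ciphertexts and the shared session file.

    The security/confounding parameters are *recovered from C1 and C0*, not
    read from the session; the session supplies only the channel secret, the
    Arnold settings, the burn-in and the recorded bit length.
    """
    if session.channel is None:
        raise ParameterError("session has no channel secret; cannot splice the mixture")
    cp = params.decrypt_confounding(c1)
    sp = params.decrypt_security(c0, cp)
    logger.debug("recovered confounding=%s security key0=%d", cp, sp.key0)

    c_dna = library.sequence_and_splice(mixture_fasta, session.channel)
    logger.debug("spliced C_DNA len=%d digest=%s", len(c_dna), _digest(c_dna))

    cfg = replace(session.data, key0=sp.key0)
    p0 = LogisticParams(float(sp.mu0), float(sp.g0))
    p1 = LogisticParams(float(sp.mu1), float(sp.g1))
    key = chaos.keystream(p0, p1, len(c_dna) * 2, session.burn_in)
    return datacipher.decrypt_data(c_dna, key, cfg)
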