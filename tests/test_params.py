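"""Parameter cipher: central-dogma confusion of the session secrets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnaotp import params
from dnaotp.errors import CorruptionError, ParameterError
from dnaotp.params import (
    ConfoundingParams,
    SecurityParams,
    confounding_encryption_trace,
    confuse_security,
    decrypt_confounding,
    decrypt_security,
    encrypt_confounding,
    insert_redundant,
    security_confusion_trace,
    serialize_params,
    strip_redundant,
)

sp_st = st.builds(
    SecurityParams,
    key0=st.integers(1, 24),
    mu0=st.floats(3.57, 3.999).map(lambda v: f"{v:.4f}"),
    g0=st.floats(0.001, 0.999).map(lambda v: f"{v:.4f}"),
    mu1=st.floats(3.57, 3.999).map(lambda v: f"{v:.4f}"),
    g1=st.floats(0.001, 0.999).map(lambda v: f"{v:.4f}"),
)
cp_st = st.builds(
    ConfoundingParams,
    key1=st.integers(1, 24),
    key2=st.integers(1, 24),
    pk=st.integers(0, 12),
)


class TestSerialization:
    def test_comma_join_no_spaces(self):
        assert serialize_params([12, "3.78", "0.51", "3.92", "0.44"]) == "12,3.78,0.51,3.92,0.44"
        assert serialize_params([4, 7, 1]) == "4,7,1"

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            serialize_params([])

    def test_texts_travel_verbatim(self):
        sp = SecurityParams(12, "3.780", "0.51", "3.92", "0.4400")
        assert sp.serialize() == "12,3.780,0.51,3.92,0.4400"
        assert SecurityParams.parse(sp.serialize()) == sp


class TestWorkedExampleTrace:
    def test_security_confusion_reproduces_every_printed_step(self, worked):
        tr = security_confusion_trace(worked.security_text, worked.key1, worked.key2, worked.pk)
        assert tr.bits == worked.step1_bits
        assert tr.dna == worked.step2_dna
        assert tr.trna == worked.step3_trna
        assert tr.rrna == worked.step3_rrna
        assert tr.trna_bits == worked.step4_trna_bits
        assert tr.rrna_bits == worked.step4_rrna_bits
        assert tr.m_values == worked.step5_m
        assert tr.n_values == worked.step5_n
        assert tr.core == worked.step6_a0
        assert len(tr.pairs) == 22

    def test_confounding_encryption_reproduces_printed_steps(self, worked):
        tr = confounding_encryption_trace(worked.confounding_text)
        assert tr.bits == worked.step8_bits
        assert tr.m_values == worked.step9_m
        assert tr.n_values == worked.step9_n
        assert tr.core == worked.step10_a1
        assert len(tr.pairs) == 5


class TestChaff:
    def test_strip_published_ciphertexts(self, worked):
        assert strip_redundant(worked.step11_c1) == worked.step10_a1
        assert strip_redundant(worked.step7_c0) == worked.step6_a0

    def test_strip_is_identity_without_chaff(self, worked):
        assert strip_redundant(worked.step6_a0) == worked.step6_a0

    def test_odd_residual_length_is_corruption(self):
        with pytest.raises(CorruptionError):
            strip_redundant("ADF")

    def test_non_amino_letters_rejected(self):
        with pytest.raises(CorruptionError):
            strip_redundant("ADZB")

    def test_default_insertion_count_quarter_of_core(self, rng, worked):
        out = insert_redundant(worked.step6_a0, rng)
        assert len(out) == 44 + 11  # round(0.25 * 44)
        assert strip_redundant(out) == worked.step6_a0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_strip_inverts_insertion_for_any_seed(self, seed, worked):
        rng = np.random.default_rng(seed)
        out = insert_redundant(worked.step10_a1, rng, count=int(rng.integers(0, 20)))
        assert strip_redundant(out) == worked.step10_a1


class TestRoundTrips:
    @given(sp=sp_st, cp=cp_st, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=1000)
    def test_encrypt_decrypt_mutually_inverse(self, sp, cp, seed):
        rng = np.random.default_rng(seed)
        c0 = confuse_security(sp, cp, rng)
        c1 = encrypt_confounding(cp, rng)
        assert decrypt_confounding(c1) == cp
        assert decrypt_security(c0, cp) == sp

    @given(cp=cp_st, s1=st.integers(0, 10**6), s2=st.integers(0, 10**6))
    @settings(max_examples=100)
    def test_decryption_independent_of_chaff_seed(self, cp, s1, s2):
        c1a = encrypt_confounding(cp, np.random.default_rng(s1))
        c1b = encrypt_confounding(cp, np.random.default_rng(s2))
        assert strip_redundant(c1a) == strip_redundant(c1b)
        assert decrypt_confounding(c1a) == decrypt_confounding(c1b) == cp

    def test_worked_example_decryption(self, worked):
        cp = decrypt_confounding(worked.step11_c1)
        assert cp == ConfoundingParams(4, 7, 1)
        sp = decrypt_security(worked.step7_c0, cp)
        assert sp == SecurityParams(12, "3.78", "0.51", "3.92", "0.44")


class TestTampering:
    def test_wrong_pk_never_silently_succeeds(self, worked):
        """Decrypting with any wrong table iteration count must not recover
        the true security parameters."""
        truth = SecurityParams(12, "3.78", "0.51", "3.92", "0.44")
        for pk in range(13):
            if pk == worked.pk:
                continue
            cp = ConfoundingParams(worked.key1, worked.key2, pk)
            try:
                recovered = decrypt_security(worked.step7_c0, cp)
            except CorruptionError:
                continue
            assert recovered != truth

    def test_single_letter_corruption_never_returns_original(self, worked):
        """Exhaustive single-letter corruption of the C1 core: every digram is
        valid in the full 16x16 grid, so corruption may decode to a *different*
        valid parameter set, but it must never silently return the original."""
        truth = ConfoundingParams(4, 7, 1)
        core = worked.step10_a1
        outcomes = {"error": 0, "different": 0}
        for i in range(len(core)):
            for letter in "ARNDCQEGHILKMFPS":
                if letter == core[i]:
                    continue
                corrupted = core[:i] + letter + core[i + 1 :]
                try:
                    recovered = decrypt_confounding(corrupted)
                except CorruptionError:
                    outcomes["error"] += 1
                    continue
                assert recovered != truth
                outcomes["different"] += 1
        # both failure modes occur in practice
        assert outcomes["error"] > 0 and outcomes["different"] > 0


class TestDomains:
    def test_security_params_validated(self):
        with pytest.raises(ParameterError):
            SecurityParams(0, "3.78", "0.51", "3.92", "0.44")
        with pytest.raises(ParameterError):
            SecurityParams(12, "3.5", "0.51", "3.92", "0.44")
        with pytest.raises(ParameterError):
            SecurityParams(12, "3.78", "1.2", "3.92", "0.44")

    def test_confounding_params_validated(self):
        with pytest.raises(ParameterError):
            ConfoundingParams(25, 7, 1)
        with pytest.raises(ParameterError):
            ConfoundingParams(4, 7, 13)

    def test_parse_rejects_malformed_texts(self):
        with pytest.raises(CorruptionError):
            ConfoundingParams.parse("4,7")
        with pytest.raises(CorruptionError):
            ConfoundingParams.parse("4,7,x")
        with pytest.raises(CorruptionError):
            SecurityParams.parse("99,3.78,0.51,3.92,0.44")
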