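"""Specificity Hamiltonian, mutation scanning and coupling decomposition."""

import numpy as np
import pytest
from conftest import random_potts, random_sequences, random_specificity_model

from coevspec import (
    PottsModel,
    SpecificityModel,
    align_query,
    coupling_decomposition,
    mutation_scan,
    score_pair,
)
from coevspec.alphabet import GAP, Alphabet
from coevspec.scoring import score_matrix


def brute_force_h(potts, prot, sub, lp, keep):
    """Term-by-term oracle: inter-block couplings + all unmasked fields."""
    h = 0.0
    for i in range(lp):
        for j in range(len(sub)):
            if keep[j]:
                h -= potts.couplings[i, lp + j, prot[i], sub[j]]
    for i in range(lp):
        h -= potts.fields[i, prot[i]]
    for j in range(len(sub)):
        if keep[j]:
            h -= potts.fields[lp + j, sub[j]]
    return h


@pytest.fixture
def model():
    return random_specificity_model(seed=0)


class TestScorePair:
    def test_matches_brute_force_summation(self, model):
        rng = np.random.default_rng(1)
        enc = model.alphabet.encode
        for masked in (False, True):
            keep = model.substrate_mask(masked)
            for p, s in random_sequences(rng, model, n=10):
                sc = score_pair(model, p, s, masked)
                expected = brute_force_h(
                    model.canonical, enc(p), enc(s), model.l_protease, keep
                ) - brute_force_h(
                    model.scrambled, enc(p), enc(s), model.l_protease, keep
                )
                assert sc.h_spec == pytest.approx(expected, abs=1e-10)
                assert sc.h_spec == pytest.approx(sc.h_can - sc.h_scram, abs=1e-12)

    def test_zero_parameters_score_zero(self):
        q, lp, ls = 3, 4, 5
        zero = lambda prov: PottsModel(
            np.zeros((lp + ls, lp + ls, q, q)), np.zeros((lp + ls, q)),
            Alphabet.reduced(q), provenance=prov,
        )
        model = SpecificityModel(zero("canonical"), zero("scrambled"), lp, ls, (2, 4))
        sc = score_pair(model, "AB"[0] * lp, "A" * ls, masked=False)
        assert sc.h_can == sc.h_scram == sc.h_spec == 0.0

    def test_identical_models_cancel(self):
        """With canonical == scrambled parameters the specificity score is
        identically zero for every pair."""
        rng = np.random.default_rng(2)
        potts = random_potts(rng, 9, 4)
        model = SpecificityModel(
            potts,
            PottsModel(potts.couplings.copy(), potts.fields.copy(),
                       potts.alphabet, provenance="scrambled"),
            4, 5, (2, 4),
        )
        for p, s in random_sequences(rng, model, n=20):
            assert score_pair(model, p, s).h_spec == pytest.approx(0.0, abs=1e-12)

    def test_swapping_models_negates_h_spec(self, model):
        rng = np.random.default_rng(3)
        swapped = SpecificityModel(
            PottsModel(model.scrambled.couplings, model.scrambled.fields,
                       model.alphabet, provenance="canonical"),
            PottsModel(model.canonical.couplings, model.canonical.fields,
                       model.alphabet, provenance="scrambled"),
            model.l_protease, model.l_substrate, model.motif_window,
        )
        for p, s in random_sequences(rng, model, n=10):
            assert score_pair(swapped, p, s).h_spec == pytest.approx(
                -score_pair(model, p, s).h_spec, abs=1e-10
            )

    def test_length_mismatch_is_error(self, model):
        with pytest.raises(ValueError, match="length"):
            score_pair(model, "A" * (model.l_protease + 1), "A" * model.l_substrate)

    def test_character_outside_alphabet_names_position(self, model):
        with pytest.raises(ValueError, match="position"):
            score_pair(model, "A" * model.l_protease, "AZ" + "A" * (model.l_substrate - 2))

    def test_mask_idempotent_when_parameters_already_masked(self, model):
        """On a model whose parameters are already zero outside the motif,
        masked and unmasked scoring agree."""
        lo, hi = model.motif_window
        lp = model.l_protease
        outside = [lp + j for j in range(model.l_substrate)
                   if not (lo - 1 <= j <= hi - 1)]
        for potts in (model.canonical, model.scrambled):
            potts.couplings[outside, :] = 0.0
            potts.couplings[:, outside] = 0.0
            potts.fields[outside] = 0.0
        rng = np.random.default_rng(4)
        for p, s in random_sequences(rng, model, n=10):
            assert score_pair(model, p, s, masked=True).h_spec == pytest.approx(
                score_pair(model, p, s, masked=False).h_spec, abs=1e-12
            )

    def test_alphabet_reordering_invariance(self, model):
        """Permuting the residue alphabet (states and letters together)
        leaves H_spec unchanged: the score depends on the sequence, not
        its integer representation."""
        rng = np.random.default_rng(5)
        q = model.alphabet.q
        perm = np.concatenate([rng.permutation(q - 1), [q - 1]])  # gap stays last
        letters = "".join(model.alphabet.letters[k] for k in perm)
        remapped = {}
        for name in ("canonical", "scrambled"):
            potts = getattr(model, name)
            e = potts.couplings[:, :, perm][:, :, :, perm]
            h = potts.fields[:, perm]
            remapped[name] = PottsModel(e, h, Alphabet("".join(letters)),
                                        provenance=name)
        model2 = SpecificityModel(
            remapped["canonical"], remapped["scrambled"],
            model.l_protease, model.l_substrate, model.motif_window,
        )
        for p, s in random_sequences(rng, model, n=10):
            assert score_pair(model2, p, s).h_spec == pytest.approx(
                score_pair(model, p, s).h_spec, abs=1e-10
            )

    def test_score_matrix_matches_score_pair(self, model):
        rng = np.random.default_rng(6)
        pairs = random_sequences(rng, model, n=4)
        prots = [p for p, _ in pairs]
        subs = [s for _, s in pairs]
        M = score_matrix(model, prots, subs, masked=True)
        for a, p in enumerate(prots):
            for b, s in enumerate(subs):
                assert M[a, b] == pytest.approx(
                    score_pair(model, p, s, masked=True).h_spec, abs=1e-10
                )


class TestMutationScan:
    def test_antisymmetry(self, model):
        # gap-free sequences: the scan proposes residues, never the gap,
        # so a gap wild type has no reverse substitution
        rng = np.random.default_rng(7)
        (p, s), = random_sequences(rng, model, n=1, gapless=True)
        effects = mutation_scan(model, p, s, targets=[3], masked=False)
        for e in effects:
            mutant = s[:2] + e.to_state + s[3:]
            back = mutation_scan(model, p, mutant, targets=[3], masked=False)
            reverse = next(x for x in back if x.to_state == e.from_state)
            assert e.delta_h + reverse.delta_h == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("masked", [False, True])
    def test_incremental_equals_full_rescoring(self, model, masked):
        rng = np.random.default_rng(8)
        (p, s), = random_sequences(rng, model, n=1)
        letters = model.alphabet.letters
        n_checked = 0
        for _ in range(100):
            pos = int(rng.integers(1, model.l_substrate + 1))
            effects = mutation_scan(model, p, s, targets=[pos], masked=masked)
            e = effects[int(rng.integers(len(effects)))]
            mutant = s[: pos - 1] + e.to_state + s[pos:]
            full = (
                score_pair(model, p, mutant, masked).h_spec
                - score_pair(model, p, s, masked).h_spec
            )
            assert e.delta_h == pytest.approx(full, abs=1e-8)
            n_checked += 1
        assert n_checked == 100

    def test_protease_block_scan(self, model):
        rng = np.random.default_rng(9)
        (p, s), = random_sequences(rng, model, n=1)
        effects = mutation_scan(model, p, s, targets=[2], masked=False,
                                block="protease")
        for e in effects[:5]:
            mutant = p[:1] + e.to_state + p[2:]
            full = (
                score_pair(model, mutant, s, masked=False).h_spec
                - score_pair(model, p, s, masked=False).h_spec
            )
            assert e.delta_h == pytest.approx(full, abs=1e-8)

    def test_gap_is_never_proposed(self, model):
        rng = np.random.default_rng(10)
        (p, s), = random_sequences(rng, model, n=1)
        effects = mutation_scan(model, p, s, masked=False)
        assert all(e.to_state != GAP for e in effects)

    def test_position_outside_block_is_error(self, model):
        rng = np.random.default_rng(11)
        (p, s), = random_sequences(rng, model, n=1)
        with pytest.raises(ValueError, match="outside"):
            mutation_scan(model, p, s, targets=[model.l_substrate + 1])


class TestCouplingDecomposition:
    def test_identical_pairs_give_zero(self, model):
        rng = np.random.default_rng(12)
        (pair,) = random_sequences(rng, model, n=1)
        contribs = coupling_decomposition(model, pair, pair, top_k=5)
        assert all(c.value == 0.0 for c in contribs)

    def test_single_site_difference_localizes(self, model):
        """When the two pairs differ only at one substrate position, every
        nonzero contribution involves that position."""
        rng = np.random.default_rng(13)
        (p, s), = random_sequences(rng, model, n=1)
        lo, _ = model.motif_window
        letters = model.alphabet.letters
        pos = lo  # inside the motif so masked scoring sees it
        other = next(c for c in letters[:-1] if c != s[pos - 1])
        s2 = s[: pos - 1] + other + s[pos:]
        contribs = coupling_decomposition(model, (p, s), (p, s2),
                                          top_k=model.l_protease * model.l_substrate)
        for c in contribs:
            if c.value != 0.0:
                assert c.substrate_position == pos

    def test_top_k_matches_exhaustive_enumeration(self, model):
        rng = np.random.default_rng(14)
        pair_a, pair_b = random_sequences(rng, model, n=2)
        enc = model.alphabet.encode
        lp = model.l_protease
        keep = model.substrate_mask(True)
        de = model.canonical.couplings - model.scrambled.couplings
        expected = []
        pa, sa = enc(pair_a[0]), enc(pair_a[1])
        pb, sb = enc(pair_b[0]), enc(pair_b[1])
        for i in range(lp):
            for j in range(model.l_substrate):
                if keep[j]:
                    ca = -de[i, lp + j, pa[i], sa[j]]
                    cb = -de[i, lp + j, pb[i], sb[j]]
                    expected.append((float(cb - ca), i + 1, j + 1))
        expected.sort()
        got = coupling_decomposition(model, pair_a, pair_b, top_k=5)
        for c, (v, i, j) in zip(got, expected[:5]):
            assert c.value == pytest.approx(v, abs=1e-12)
            assert (c.protease_position, c.substrate_position) == (i, j)

    def test_contributions_plus_fields_reproduce_h_spec_difference(self, model):
        rng = np.random.default_rng(15)
        pair_a, pair_b = random_sequences(rng, model, n=2)
        all_contribs = coupling_decomposition(
            model, pair_a, pair_b,
            top_k=model.l_protease * model.l_substrate, masked=False,
        )
        coupling_part = sum(c.value for c in all_contribs)
        dh = model.canonical.fields - model.scrambled.fields
        enc = model.alphabet.encode
        lp = model.l_protease
        field_part = 0.0
        for seqs, sign in ((pair_b, 1.0), (pair_a, -1.0)):
            pe, se = enc(seqs[0]), enc(seqs[1])
            field_part += sign * (
                -dh[np.arange(lp), pe].sum()
                - dh[lp + np.arange(model.l_substrate), se].sum()
            )
        full = (
            score_pair(model, *pair_b, masked=False).h_spec
            - score_pair(model, *pair_a, masked=False).h_spec
        )
        assert coupling_part + field_part == pytest.approx(full, abs=1e-8)


class TestAlignQuery:
    def test_training_row_round_trip(self, small_scorer):
        row = small_scorer.model_.protease_profile[0]
        assert small_scorer.align_query(row.replace(GAP, ""), "protease") == row

    def test_motif_placed_in_window(self, small_scorer):
        model = small_scorer.model_
        lo, hi = model.motif_window
        motif = "A" * (hi - lo + 1)
        aligned = small_scorer.align_query(motif, "substrate")
        assert len(aligned) == model.l_substrate
        assert aligned[lo - 1 : hi] == motif
        assert set(aligned[: lo - 1] + aligned[hi:]) <= {GAP}

    def test_empty_query_is_error(self, small_scorer):
        with pytest.raises(ValueError, match="empty"):
            small_scorer.align_query("", "protease")

    def test_bad_role_is_error(self, small_scorer):
        with pytest.raises(ValueError, match="role"):
            small_scorer.align_query("AAA", "enzyme")


def test_model_serialization_round_trip(tmp_path, small_scorer):
    model = small_scorer.model_
    path = tmp_path / "model.npz"
    model.save(path)
    back = SpecificityModel.load(path)
    rng = np.random.default_rng(16)
    for p, s in random_sequences(rng, model, n=5):
        assert score_pair(back, p, s).h_spec == pytest.approx(
            score_pair(model, p, s).h_spec, abs=1e-12
        )
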