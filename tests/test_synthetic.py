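"""The fixture generator: determinism, planted composition, conservation
coupling, self-consistency and complexes."""
import numpy as np
import pytest

from mprap.accessibility import (
    BurialState,
    compute_sasa,
    load_reference_table,
    relative_accessibility,
)
from mprap.conservation import normalize_rates
from mprap.errors import DomainError, MprapError
from mprap.structio import HYDROPHOBIC, Region, read_structure, write_structure
from mprap.synthetic import (
    _ca_trace,
    _family_params,
    generate_alignment,
    generate_complex,
    generate_protein,
    load_corpus,
    sample_aa,
    write_bundle,
    write_corpus,
)


class TestGeometry:
    def test_tm_helices_span_membrane_slab(self, small_bundle):
        helix = small_bundle.truth[
            small_bundle.truth["segment"].str.startswith("helix")]
        assert helix["z"].abs().max() <= 17.0
        assert helix["z"].abs().min() <= 2.0

    def test_all_three_regions_populated(self, small_bundle):
        regions = set(small_bundle.truth["region"])
        assert regions == {r.value for r in Region}

    def test_byte_identical_regeneration(self, spec, tmp_path):
        b1 = generate_protein(spec, 4)
        b2 = generate_protein(spec, 4)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(b1.structure, p1)
        write_structure(b2.structure, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert b1.sequence == b2.sequence
        np.testing.assert_array_equal(b1.pssm.scores, b2.pssm.scores)

    def test_inward_facing_residues_more_buried(self, small_bundle):
        t = small_bundle.truth
        inward = t[t["facing"] == "inward"]["rsa_single"]
        outward = t[t["facing"] == "outward"]["rsa_single"]
        assert inward.mean() < outward.mean()

    def test_single_helix_rejected(self, spec):
        import dataclasses
        bad = dataclasses.replace(spec, helices_range=(1, 1))
        with pytest.raises(MprapError):
            _ca_trace(bad, _family_params(bad, 0) | {"n_helices": 1},
                      np.random.default_rng(0))


class TestComposition:
    @pytest.mark.parametrize("region,burial,lo,hi", [
        (Region.CORE, BurialState.EXPOSED, 0.70, 0.76),
        (Region.NONMEMBRANE, BurialState.EXPOSED, 0.16, 0.22),
    ])
    def test_hydrophobic_fraction_targets(self, spec, region, burial, lo, hi):
        rng = np.random.default_rng(0)
        draws = [sample_aa(region, burial, spec, rng) for _ in range(10_000)]
        frac = np.mean([aa in HYDROPHOBIC for aa in draws])
        assert lo <= frac <= hi

    def test_pure_hydrophobic_cell_emits_only_hydrophobics(self, spec):
        import dataclasses
        full = dataclasses.replace(
            spec, composition={k: 1.0 for k in spec.composition})
        rng = np.random.default_rng(1)
        draws = {sample_aa(Region.CORE, BurialState.BURIED, full, rng)
                 for _ in range(500)}
        assert draws <= set("AFILMV")

    def test_exposed_composition_gap_larger_than_buried_gap(self, corpus):
        """Membrane-vs-aqueous composition differs far more for exposed
        sites than for buried ones."""
        t = __import__("pandas").concat([b.truth for b in corpus])
        t["hyd"] = t["aa"].isin(list(HYDROPHOBIC))
        def frac(region, state):
            sel = t[(t["region"] == region) & (t["state_single"] == state)]
            return sel["hyd"].mean()
        gap_exposed = frac("core", "exposed") - frac("nonmembrane", "exposed")
        gap_buried = frac("core", "buried") - frac("nonmembrane", "buried")
        assert gap_exposed > gap_buried > 0


class TestConsistency:
    def test_truth_rsa_matches_sasa_on_emitted_pdb(self, spec, tmp_path):
        bundle = generate_protein(spec, 7)
        write_bundle(bundle, tmp_path)
        back = read_structure(tmp_path / f"{bundle.name}.pdb")
        prof = relative_accessibility(
            compute_sasa(back, probe=spec.probe, context="single_chain"),
            load_reference_table(spec.probe))
        rsa = prof.rsa_map()
        for row in bundle.truth.itertuples():
            assert rsa[(row.chain, row.res_index)] == pytest.approx(
                row.rsa_single, abs=1e-3)

    def test_corpus_write_load_round_trip(self, spec, tmp_path):
        bundles = [generate_protein(spec, i) for i in range(2)]
        bundles.append(generate_complex(spec, 100))
        write_corpus(bundles, tmp_path, spec)
        back = load_corpus(tmp_path)
        assert [b.name for b in back] == [b.name for b in bundles]
        for orig, re in zip(bundles, back):
            assert re.sequence == orig.sequence
            assert re.is_complex == orig.is_complex
            np.testing.assert_array_equal(re.pssm.scores, orig.pssm.scores)
            np.testing.assert_allclose(re.z, orig.z, atol=5e-4)


class TestConservationCoupling:
    def test_planted_linear_coupling_recovered(self, small_bundle):
        r = normalize_rates(small_bundle.raw_rates).rates
        rsa = small_bundle.truth["rsa_single"].to_numpy()
        assert np.corrcoef(r, rsa)[0, 1] > 0.5

    def test_zero_coupling_gives_null_signal(self, spec):
        import dataclasses
        null = dataclasses.replace(spec, rate_coupling=0.0, noise_sd=0.0)
        bundle = generate_protein(spec, 3)
        rng = np.random.default_rng(0)
        _, raw, _ = generate_alignment(
            bundle.sequence, bundle.truth["rsa_single"].to_numpy(),
            null, rng)
        r = normalize_rates(raw).rates
        rsa = bundle.truth["rsa_single"].to_numpy()
        assert abs(np.corrcoef(r, rsa)[0, 1]) < 0.25

    def test_fully_conserved_homologs_peak_pssm_at_query(self, spec):
        import dataclasses
        frozen = dataclasses.replace(spec, rate_base=0.0, rate_coupling=0.0,
                                     noise_sd=0.0)
        bundle = generate_protein(spec, 5)
        rng = np.random.default_rng(0)
        _, _, pssm = generate_alignment(
            bundle.sequence, bundle.truth["rsa_single"].to_numpy(),
            frozen, rng)
        from mprap.features import PSSM_ALPHABET
        for letter, row in zip(pssm.letters, pssm.scores):
            assert np.argmax(row) == PSSM_ALPHABET.index(letter)

    def test_shallow_alignment_rejected(self, spec, small_bundle):
        import dataclasses
        shallow = dataclasses.replace(spec, alignment_depth=3)
        with pytest.raises(DomainError):
            generate_alignment(small_bundle.sequence,
                               small_bundle.truth["rsa_single"].to_numpy(),
                               shallow, np.random.default_rng(0))


class TestComplexes:
    def test_planted_interfaces_detectable(self, complexes):
        for c in complexes:
            n_if = (c.truth["interface"] == "interface").sum()
            assert n_if >= 10

    def test_interface_subset_of_single_chain_exposed(self, complexes):
        for c in complexes:
            iface = c.truth[c.truth["interface"] == "interface"]
            assert (iface["rsa_single"] > 25.0).all()

    def test_distant_chains_share_no_interface(self, spec):
        far = generate_complex(spec, 101, separation=100.0)
        assert (far.truth["interface"] == "interface").sum() == 0
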