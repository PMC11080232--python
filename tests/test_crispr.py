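"""CRISPR array detection, spacer extraction, protospacer matching, and
strain-level linkage with the co-occurrence constraint."""

import numpy as np
import pandas as pd
import pytest

from rumivirome.crispr import (
    classify_specificity,
    detect_crispr_arrays,
    extract_spacers,
    link_hosts,
    match_protospacers,
    reverse_complement,
    strain_present,
    votu_present,
)
from rumivirome.types import CoverageProfile, GenomeRecord, SpacerMatch


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _planted_array(rng, repeat_len=30, spacer_lens=(34, 34, 34)):
    repeat = _random_seq(rng, repeat_len)
    spacers = [_random_seq(rng, L) for L in spacer_lens]
    array = repeat + "".join(sp + repeat for sp in spacers)
    return repeat, spacers, array


class TestDetector:
    def test_planted_array_recovered_verbatim(self):
        rng = np.random.default_rng(0)
        repeat, spacers, array = _planted_array(rng)
        seq = _random_seq(rng, 3000) + array + _random_seq(rng, 3000)
        (arr,) = detect_crispr_arrays("c", seq)
        assert arr.consensus_repeat == repeat
        assert arr.spacer_sequences == spacers

    def test_random_sequence_yields_nothing(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert detect_crispr_arrays("c", _random_seq(rng, 10_000)) == []

    def test_tandem_repeat_rejected(self):
        rng = np.random.default_rng(2)
        repeat = _random_seq(rng, 30)
        spacer = _random_seq(rng, 34)  # identical spacers = tandem repeat
        array = repeat + (spacer + repeat) * 3
        seq = _random_seq(rng, 2000) + array + _random_seq(rng, 2000)
        assert detect_crispr_arrays("c", seq) == []

    def test_detects_all_planted_community_arrays(self, community):
        truth = {a.seq_id: a for a in community.crispr_truth}
        for seq_id, seq in community.genome_seqs.items():
            found = detect_crispr_arrays(seq_id, seq)
            if seq_id in truth:
                want = truth[seq_id].spacer_sequences
                assert any(a.spacer_sequences == want for a in found)
            else:
                assert found == []


class TestExtractSpacers:
    def test_length_boundary_inclusive_at_30(self):
        rng = np.random.default_rng(3)
        repeat, _, _ = _planted_array(rng)
        from rumivirome.types import CrisprArray

        spacers = [_random_seq(rng, 28), _random_seq(rng, 30), _random_seq(rng, 45)]
        pos = 0
        reps, spcs = [], []
        for i in range(4):
            reps.append((pos, pos + 30, repeat))
            pos += 30
            if i < 3:
                spcs.append((pos, pos + len(spacers[i]), spacers[i]))
                pos += len(spacers[i])
        arr = CrisprArray("a0", "c", reps, spcs, repeat)
        out = extract_spacers([arr], min_len=30)
        assert set(out.values()) == {spacers[1], spacers[2]}
        assert set(out) == {"a0:1", "a0:2"}


def hamming_scan_oracle(spacers, votus, max_mm=1):
    """Independent brute-force scan: per-position Hamming over both strands."""
    hits = set()
    for votu_id, target in votus.items():
        for sid, sp in spacers.items():
            for strand, probe in (("+", sp), ("-", reverse_complement(sp))):
                for pos in range(len(target) - len(probe) + 1):
                    mm = sum(1 for a, b in zip(probe, target[pos : pos + len(probe)]) if a != b)
                    if mm <= max_mm:
                        hits.add((sid, votu_id, pos, strand, mm))
    return hits


class TestProtospacerMatching:
    def test_forward_verbatim_hit(self):
        rng = np.random.default_rng(4)
        target = _random_seq(rng, 500)
        sp = target[100:135]
        (hit,) = match_protospacers({"s:0": sp}, {"v": target}, max_mismatches=0)
        assert (hit.position, hit.strand, hit.mismatches) == (100, "+", 0)

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(5)
        target = _random_seq(rng, 500)
        sp = reverse_complement(target[200:232])
        (hit,) = match_protospacers({"s:0": sp}, {"v": target}, max_mismatches=0)
        assert (hit.position, hit.strand) == (200, "-")

    def test_equals_hamming_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(6)
        for rep in range(20):
            target = _random_seq(rng, 400)
            spacers = {}
            for i in range(5):
                L = int(rng.integers(30, 42))
                start = int(rng.integers(0, 400 - L))
                sp = target[start : start + L]
                kind = rng.integers(3)
                if kind == 1:  # plant one mismatch
                    j = int(rng.integers(L))
                    sp = sp[:j] + rng.choice([b for b in "ACGT" if b != sp[j]]) + sp[j + 1 :]
                elif kind == 2:  # unrelated spacer
                    sp = _random_seq(rng, L)
                spacers[f"a{rep}:{i}"] = sp
            got = {
                (h.spacer_id, h.votu_id, h.position, h.strand, h.mismatches)
                for h in match_protospacers(spacers, {"v": target})
            }
            assert got == hamming_scan_oracle(spacers, {"v": target})

    def test_non_acgt_spacer_rejected(self):
        with pytest.raises(ValueError, match="s:0"):
            match_protospacers({"s:0": "ACGTN" * 8}, {"v": "ACGT" * 100})


class TestPresenceGates:
    def _mag(self):
        return GenomeRecord("m1", "spX", "m1", (("c1", 1000),))

    def test_present(self):
        cov = {"c1": CoverageProfile("c1", np.repeat([1, 0], [600, 400]))}
        assert strain_present(self._mag(), cov, total_reads=100)

    def test_breadth_gate(self):
        cov = {"c1": CoverageProfile("c1", np.repeat([9, 0], [400, 600]))}
        assert not strain_present(self._mag(), cov, total_reads=1000)

    def test_read_gate(self):
        cov = {"c1": CoverageProfile("c1", np.repeat([1, 0], [600, 400]))}
        assert not strain_present(self._mag(), cov, total_reads=3)

    def test_missing_coverage_warns_absent(self):
        with pytest.warns(UserWarning, match="no coverage"):
            assert not strain_present(self._mag(), {})

    @pytest.mark.parametrize("frac,expected", [(0.75, True), (0.69, False), (0.0, False)])
    def test_votu_presence_boundary(self, frac, expected):
        depths = np.repeat([1, 0], [int(frac * 1000), 1000 - int(frac * 1000)])
        assert votu_present("v", CoverageProfile("v", depths)) is expected


class TestLinkage:
    def _presence(self, data, entities):
        return pd.DataFrame(data, index=[f"s{i}" for i in range(len(data))],
                            columns=entities, dtype=bool)

    def test_match_without_cooccurrence_no_linkage(self):
        matches = [SpacerMatch("arr1:0", "v1", 5, "+", 0)]
        presence = self._presence([[True, False], [False, True]], ["m1", "v1"])
        assert link_hosts(matches, {"arr1": "m1"}, presence) == []

    def test_supporting_samples_listed(self):
        matches = [SpacerMatch("arr1:0", "v1", 5, "+", 0)]
        presence = self._presence(
            [[True, True], [False, True], [True, True]], ["m1", "v1"]
        )
        (lk,) = link_hosts(matches, {"arr1": "m1"}, presence)
        assert lk.supporting_samples == {"s0", "s2"}

    def test_single_mismatch_never_links(self):
        matches = [SpacerMatch("arr1:0", "v1", 5, "+", 1)]
        presence = self._presence([[True, True]], ["m1", "v1"])
        assert link_hosts(matches, {"arr1": "m1"}, presence) == []


class TestSpecificity:
    def catalog(self):
        return [
            GenomeRecord("x1", "spX", "x1", (("x1c", 100),)),
            GenomeRecord("x2", "spX", "x2", (("x2c", 100),)),
            GenomeRecord("x3", "spX", "x3", (("x3c", 100),)),
            GenomeRecord("y1", "spY", "y1", (("y1c", 100),)),
        ]

    def test_hand_worked_five_sample_fixture(self):
        # linkages: vA-x1, vB-x1, vB-y1, vC-x2
        linkages_spec = [("vA", "x1"), ("vB", "x1"), ("vB", "y1"), ("vC", "x2")]
        from rumivirome.types import HostLinkage

        linkages = [
            HostLinkage(mag, votu, frozenset({"s0"}), frozenset({f"{mag}:0"}))
            for votu, mag in linkages_spec
        ]
        cols = ["x1", "x2", "x3", "y1", "vA", "vB", "vC"]
        presence = pd.DataFrame(
            [
                # s0: only x1 present; vA -> single_strain
                [1, 0, 0, 0, 1, 0, 0],
                # s1: x1 and y1 present, vB links both -> multi_species
                [1, 0, 0, 1, 0, 1, 0],
                # s2: x2 and x3 present, vC links only x2 -> conspecific_partial
                [0, 1, 1, 0, 0, 0, 1],
                # s3: x1 alone with vA and vB -> two single_strain votus
                [1, 0, 0, 0, 1, 1, 0],
                # s4: nothing linked present -> sample dropped
                [0, 0, 1, 0, 1, 0, 0],
            ],
            index=[f"s{i}" for i in range(5)], columns=cols, dtype=bool,
        )
        out = classify_specificity(linkages, presence, self.catalog())
        assert list(out.index) == ["s0", "s1", "s2", "s3"]
        assert out.loc["s0", "single_strain"] == 1.0
        assert out.loc["s1", "multi_species"] == 1.0
        assert out.loc["s2", "conspecific_partial"] == 1.0
        assert out.loc["s3", "single_strain"] == 1.0
        sums = out[["single_strain", "multi_species", "conspecific_partial"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_fractions_sum_to_one_on_random_fixtures(self, rng):
        from rumivirome.types import HostLinkage

        catalog = self.catalog()
        mags = [g.mag_id for g in catalog]
        votus = ["v1", "v2", "v3"]
        linkages = [
            HostLinkage(m, v, frozenset({"s0"}), frozenset({f"{m}:0"}))
            for m in mags for v in votus if rng.random() < 0.5
        ]
        if not linkages:
            return
        presence = pd.DataFrame(
            rng.random((6, len(mags) + len(votus))) < 0.6,
            index=[f"s{i}" for i in range(6)], columns=mags + votus,
        )
        out = classify_specificity(linkages, presence, catalog)
        if len(out):
            sums = out[["single_strain", "multi_species", "conspecific_partial"]].sum(axis=1)
            assert np.allclose(sums, 1.0)
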