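"""RSCU, ENC, the expected-ENC curve, and CAI."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cubkit.datasets import expression_group_counts, load_expression_groups
from cubkit.genetic_code import (
    AA_OF,
    DEGENERACY_CLASSES,
    FAMILIES,
    MULTI_CODON_AAS,
    SENSE_CODONS,
    to_dna,
)
from cubkit.indices import (
    CaiModel,
    build_cai_model,
    cai,
    enc,
    enc_deviation,
    expected_enc,
    rscu,
    weights_from_reference,
)
from cubkit.sequence_io import CodonCounts
from cubkit.synthetic import DEFAULT_PREFERRED


def cc(mapping):
    return CodonCounts(counts=dict(mapping))


def one_codon_per_family_counts(n_each=50):
    """A gene that uses exactly the first codon of each of the 20 families."""
    return cc({FAMILIES[aa][0]: n_each for aa in FAMILIES})


def uniform_usage_counts(n_each=100):
    return cc({codon: n_each for codon in SENSE_CODONS})


class TestRscu:
    def test_published_alanine_worked_example(self):
        table = rscu(cc({"GCA": 3868, "GCC": 2761, "GCG": 1464, "GCT": 4338}))
        assert round(table.get("GCA"), 3) == 1.245

    def test_uniform_family_is_unbiased(self):
        table = rscu(cc({"GGA": 5, "GGC": 5, "GGG": 5, "GGT": 5}))
        for codon in ("GGA", "GGC", "GGG", "GGT"):
            assert table.get(codon) == pytest.approx(1.0)

    def test_twofold_maximal_bias_hits_k(self):
        table = rscu(cc({"AAA": 7, "AAG": 0}))
        assert table.get("AAA") == pytest.approx(2.0)
        assert table.get("AAG") == pytest.approx(0.0)

    def test_unobserved_family_is_missing_not_zero(self):
        table = rscu(cc({"AAA": 3}))
        assert math.isnan(table.get("GGA"))

    def test_met_trp_are_one_when_observed(self):
        table = rscu(cc({"ATG": 4, "TGG": 1}))
        assert table.get("ATG") == 1.0 and table.get("TGG") == 1.0

    @given(
        st.dictionaries(
            st.sampled_from(SENSE_CODONS), st.integers(0, 40), max_size=61
        )
    )
    def test_family_mean_normalization(self, counts):
        """Every observed family's RSCU values average to exactly 1 and
        stay within [0, k]."""
        table = rscu(cc(counts))
        for aa in MULTI_CODON_AAS:
            fam = FAMILIES[aa]
            values = [table.get(c) for c in fam]
            if any(counts.get(c, 0) for c in fam):
                assert np.mean(values) == pytest.approx(1.0, abs=1e-12)
                assert all(0 <= v <= len(fam) for v in values)
            else:
                assert all(math.isnan(v) for v in values)

    def test_full_published_table_reproduced(self):
        """Computed group RSCU matches every printed cell of the published
        high/low expression comparison to 3-decimal rounding."""
        df = load_expression_groups()
        high, low = expression_group_counts()
        tables = {"high": rscu(high), "low": rscu(low)}
        for _, row in df.iterrows():
            codon = to_dna(row["codon"])
            for group in ("high", "low"):
                got = tables[group].get(codon)
                assert got == pytest.approx(
                    row[f"{group}_rscu"], abs=0.0015
                ), f"{row['codon']} {group}"


def reference_enc(counts: CodonCounts) -> float:
    """Independent ENC implementation, straight from the textbook
    formula with explicit loops (the oracle for the packaged one)."""
    class_f = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            ns = [counts.get(c) for c in FAMILIES[aa]]
            n = sum(ns)
            if n <= 1:
                continue
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            class_f[k] = sum(fs) / len(fs)
    if 3 not in class_f and {2, 4} <= set(class_f):
        class_f[3] = (class_f[2] + class_f[4]) / 2
    if not {2, 3, 4, 6} <= set(class_f):
        return float("nan")
    sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    return min(2 + sum(sizes[k] / class_f[k] for k in (2, 3, 4, 6)), 61.0)


class TestEnc:
    def test_one_codon_per_family_gives_20(self):
        result = enc(one_codon_per_family_counts())
        assert result.enc_obs == pytest.approx(20.0)

    def test_uniform_usage_gives_61(self):
        result = enc(uniform_usage_counts(200))
        assert result.enc_obs == pytest.approx(61.0)

    def test_uniform_raw_estimate_converges_to_61(self):
        """Finite-sample departure of the raw estimator from 61 vanishes
        as the gene grows; the capped value never exceeds 61."""
        gaps = []
        for n_each in (5, 50, 1000):
            counts = cc({codon: n_each for codon in SENSE_CODONS})
            result = enc(counts)
            assert result.enc_obs <= 61.0
            sizes = {2: 9, 3: 1, 4: 5, 6: 3}
            raw = 2 + sum(
                sizes[k] / result.f_bar_by_class[k] for k in (2, 3, 4, 6)
            )
            gaps.append(abs(raw - 61.0))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05

    def test_too_few_codons_flagged_missing(self):
        result = enc(cc({"AAA": 5, "AAG": 5}), min_codons=30)
        assert math.isnan(result.enc_obs)
        assert "TOO_FEW_CODONS" in result.flags

    def test_missing_degeneracy_class_flagged(self):
        # plenty of codons but no six-fold family at all
        counts = {FAMILIES[aa][0]: 10 for aa in FAMILIES if len(FAMILIES[aa]) != 6}
        counts.update({FAMILIES[aa][1]: 10 for aa in FAMILIES if len(FAMILIES[aa]) == 4})
        result = enc(cc(counts))
        assert math.isnan(result.enc_obs)
        assert "MISSING_CLASS_6" in result.flags

    def test_matches_independent_implementation(self, mutation_counts):
        for counts in list(mutation_counts.values())[:50]:
            ours = enc(counts).enc_obs
            oracle = reference_enc(counts)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_enc_decreases_with_selection_strength(self):
        """Average ENC over 200 genes falls monotonically as the planted
        selection strength rises."""
        from cubkit.sequence_io import count_codons
        from cubkit.synthetic import generate_genome, selection_spec

        means = []
        for s in (0.0, 0.75, 1.5):
            records, _ = generate_genome(
                selection_spec(n_genes=200, seed=101, s_high=s, p_high=1.0)
            )
            values = [enc(count_codons(r)).enc_obs for r in records]
            means.append(np.nanmean(values))
        assert means[0] > means[1] > means[2]


class TestExpectedEnc:
    @pytest.mark.parametrize("s, value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_curve_values(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    @pytest.mark.parametrize("s", [0.1, 0.25, 0.42, 0.73])
    def test_symmetry_identity(self, s):
        """expected_enc(s) - expected_enc(1-s) = s - (1-s) exactly."""
        assert expected_enc(s) - expected_enc(1 - s) == pytest.approx(
            s - (1 - s), abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    def test_deviation_examples(self):
        assert enc_deviation(expected_enc(0.3), 0.3) == 0.0
        assert enc_deviation(54.45, 0.5) == pytest.approx(0.1)
        assert math.isnan(enc_deviation(float("nan"), 0.5))


class TestCai:
    def make_model(self, weights):
        full = {}
        for aa in MULTI_CODON_AAS:
            for codon in FAMILIES[aa]:
                full[codon] = weights.get(codon, 1.0)
        full["ATG"] = full["TGG"] = 1.0
        return CaiModel(weights=full, reference_ids=())

    def test_all_weight_one_codons_give_cai_one(self):
        model = self.make_model({})
        assert cai(cc({"AAA": 10, "GGA": 5}), model) == pytest.approx(1.0)

    def test_geometric_mean_hand_example(self):
        model = self.make_model({"AAG": 0.25})
        assert cai(cc({"AAA": 6, "AAG": 6}), model) == pytest.approx(0.5)

    def test_met_trp_do_not_dilute(self):
        model = self.make_model({"AAG": 0.25})
        with_mw = cai(cc({"AAA": 6, "AAG": 6, "ATG": 50, "TGG": 50}), model)
        assert with_mw == pytest.approx(0.5)

    def test_no_eligible_codons_is_missing(self):
        model = self.make_model({})
        assert math.isnan(cai(cc({"ATG": 10}), model))

    def test_invariant_under_count_scaling(self, selection_counts):
        genes = list(selection_counts.items())
        model = build_cai_model(genes)
        counts = genes[0][1]
        scaled = cc({k: 7 * v for k, v in counts.counts.items()})
        assert cai(scaled, model) == pytest.approx(cai(counts, model), abs=1e-12)

    def test_matches_logdomain_bruteforce(self, selection_counts):
        genes = list(selection_counts.items())
        model = build_cai_model(genes)
        for _, counts in genes[:100]:
            total = 0
            log_sum = 0.0
            for codon, n in counts.counts.items():
                if codon in AA_OF and len(FAMILIES[AA_OF[codon]]) > 1:
                    log_sum += n * math.log(model.weights[codon])
                    total += n
            brute = math.exp(log_sum / total)
            assert cai(counts, model) == pytest.approx(brute, abs=1e-12)


class TestCaiModel:
    def test_single_codon_reference_weights(self):
        model = weights_from_reference(one_codon_per_family_counts())
        for aa in MULTI_CODON_AAS:
            fam = FAMILIES[aa]
            assert model.weights[fam[0]] == 1.0
            for sibling in fam[1:]:
                assert model.weights[sibling] == 0.01

    def test_uniform_reference_weights_all_one(self):
        model = weights_from_reference(uniform_usage_counts())
        for aa in MULTI_CODON_AAS:
            for codon in FAMILIES[aa]:
                assert model.weights[codon] == pytest.approx(1.0)

    def test_family_max_weight_is_one(self, selection_counts):
        model = build_cai_model(list(selection_counts.items()))
        for aa in MULTI_CODON_AAS:
            top = max(model.weights[c] for c in FAMILIES[aa])
            assert top == pytest.approx(1.0)
            assert all(model.weights[c] >= model.floor for c in FAMILIES[aa])

    def test_too_small_reference_rejected(self, selection_counts):
        genes = list(selection_counts.items())[:60]  # 5% of 60 -> 3 < 5
        with pytest.raises(ValueError, match="reference"):
            build_cai_model(genes)

    def test_recovers_planted_preferred_codons(self, selection_counts):
        """The argmax-weight codon of each family matches the planted
        preferred set when selection strength is 1."""
        model = build_cai_model(list(selection_counts.items()))
        recovered = {
            max(FAMILIES[aa], key=lambda c: model.weights[c])
            for aa in MULTI_CODON_AAS
        }
        overlap = recovered & set(DEFAULT_PREFERRED)
        assert len(overlap) >= 0.95 * len(DEFAULT_PREFERRED)
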