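import numpy as np
import pytest

from dumbopt import (
    HarmonizationConfig,
    dumb_optimize,
    fully_optimize,
    random_control,
    verify_synonymy,
)
from dumbopt.codon_usage import STANDARD_CODE
from dumbopt.errors import (
    ConfigurationError,
    PrematureStopError,
    SequenceAlphabetError,
    SequenceFrameError,
)

from conftest import make_table
from _oracles import brute_force_codon_choice

LEU_HOST = {"CTG": 0.50, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04,
            "TTA": 0.13, "TTG": 0.13}
LEU_NATIVE = {"CTG": 0.40, "CTT": 0.12, "CTC": 0.12, "CTA": 0.12,
              "TTA": 0.12, "TTG": 0.12}


@pytest.fixture(scope="module")
def leu_tables():
    return make_table("native", {"L": LEU_NATIVE}), make_table("host", {"L": LEU_HOST})


class TestDumbOptimize:
    def test_frequency_matching_picks_nearest_fraction(self, leu_tables):
        # native CTG carries 0.40; among host fractions 0.50 is nearest
        native, host = leu_tables
        res = dumb_optimize("CTG", native, host, HarmonizationConfig(threshold=0.05))
        rec = res.records[0]
        assert rec.chosen_codon == "CTG"
        assert rec.match_error == pytest.approx(0.10)
        assert not rec.constrained

    def test_identity_when_tables_match(self, human_table, random_gene_factory):
        gene = random_gene_factory(seed=11, length=200)
        res = dumb_optimize(gene, human_table, human_table)
        assert res.output_sequence == gene
        assert res.total_match_error == pytest.approx(0.0)

    def test_singleton_family_retained(self, human_table, ecoli_table):
        res = dumb_optimize("ATGTGG", human_table, ecoli_table)
        assert res.output_sequence == "ATGTGG"
        assert all(r.match_error == 0.0 for r in res.records)

    def test_final_stop_copied_verbatim(self, human_table, ecoli_table):
        res = dumb_optimize("ATGTAG", human_table, ecoli_table)
        assert res.output_sequence.endswith("TAG")

    def test_absolute_floor_excludes_rare_codon_and_flags(self):
        # native wants 0.03; the matching host codon sits below the floor
        native = make_table("n", {"L": {"CTA": 0.03, "CTG": 0.50, "CTT": 0.15,
                                        "CTC": 0.12, "TTA": 0.10, "TTG": 0.10}})
        host = make_table("h", {"L": {"CTA": 0.03, "CTG": 0.50, "CTT": 0.15,
                                      "CTC": 0.12, "TTA": 0.10, "TTG": 0.10}})
        cfg = HarmonizationConfig(threshold=0.05, threshold_mode="absolute_floor")
        rec = dumb_optimize("CTA", native, host, cfg).records[0]
        assert rec.chosen_codon != "CTA"
        assert rec.constrained

    def test_relaxation_when_no_codon_clears_floor(self):
        native = make_table("n", {"L": {"CTG": 0.95, "CTT": 0.01, "CTC": 0.01,
                                        "CTA": 0.01, "TTA": 0.01, "TTG": 0.01}})
        host = make_table("h", {"L": {"CTG": 0.30, "CTT": 0.20, "CTC": 0.20,
                                      "CTA": 0.10, "TTA": 0.10, "TTG": 0.10}})
        cfg = HarmonizationConfig(threshold=0.9, threshold_mode="absolute_floor")
        rec = dumb_optimize("CTG", native, host, cfg).records[0]
        assert rec.constrained
        assert rec.chosen_codon == "CTG"  # best match once relaxed

    @pytest.mark.parametrize(
        "seq,err",
        [
            ("ATGC", SequenceFrameError),
            ("ATGNNN", SequenceAlphabetError),
            ("TAAATG", PrematureStopError),
        ],
    )
    def test_invalid_sequences_rejected(self, seq, err, human_table, ecoli_table):
        with pytest.raises(err):
            dumb_optimize(seq, human_table, ecoli_table)

    def test_premature_stop_reports_position(self, human_table, ecoli_table):
        with pytest.raises(PrematureStopError) as exc:
            dumb_optimize("ATGTGAATG", human_table, ecoli_table)
        assert exc.value.position == 1

    def test_audit_frame_schema(self, human_table, ecoli_table, random_gene_factory):
        gene = random_gene_factory(seed=4, length=30)
        frame = dumb_optimize(gene, human_table, ecoli_table).to_frame()
        assert list(frame.columns) == [
            "position", "native_codon", "native_fraction", "chosen_codon",
            "host_fraction", "match_error", "constrained",
        ]
        assert len(frame) == len(gene) // 3


class TestFullyOptimize:
    def test_single_codon_amino_acid(self, ecoli_table):
        assert fully_optimize("ATG", ecoli_table).output_sequence == "ATG"

    def test_leucine_goes_to_host_maximum(self, ecoli_table):
        res = fully_optimize("TTATTGCTC", ecoli_table)
        assert res.output_sequence == "CTGCTGCTG"

    def test_idempotence(self, ecoli_table, random_gene_factory):
        gene = random_gene_factory(seed=5, length=80)
        once = fully_optimize(gene, ecoli_table).output_sequence
        assert fully_optimize(once, ecoli_table).output_sequence == once


class TestRandomControl:
    def test_deterministic_under_seed(self, ecoli_table, random_gene_factory):
        gene = random_gene_factory(seed=6, length=60)
        a = random_control(gene, ecoli_table, seed=42).output_sequence
        b = random_control(gene, ecoli_table, seed=42).output_sequence
        assert a == b

    def test_singleton_only_sequence_unchanged(self, ecoli_table):
        seq = "ATGTGG" * 5
        for seed in (0, 1, 2):
            assert random_control(seq, ecoli_table, seed=seed).output_sequence == seq

    def test_missing_seed_rejected(self, ecoli_table):
        with pytest.raises(ConfigurationError):
            random_control("ATGCTG", ecoli_table)

    def test_uniform_family_sampling(self, ecoli_table):
        # one Leu position drawn 10,000 times: each codon ≈ 1/6 ± 3σ binomial
        n = 10_000
        counts = {}
        for seed in range(n):
            codon = random_control("CTG", ecoli_table, seed=seed).output_sequence
            counts[codon] = counts.get(codon, 0) + 1
        p = 1.0 / 6.0
        sigma = np.sqrt(n * p * (1 - p))
        assert len(counts) == 6
        for c, k in counts.items():
            assert abs(k - n * p) < 3 * sigma, (c, k)


class TestVerifySynonymy:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ATGCTG", "ATGTTA", True), ("ATG", "ATC", False), ("ATGCTG", "ATGCTG", True)],
    )
    def test_examples(self, a, b, expected):
        assert verify_synonymy(a, b) is expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            verify_synonymy("ATG", "ATGCTG")


class TestProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_modes_preserve_translation(
        self, seed, human_table, ecoli_table, random_gene_factory
    ):
        rng = np.random.default_rng(seed)
        gene = random_gene_factory(seed=seed, length=int(rng.integers(20, 150)))
        for res in (
            dumb_optimize(gene, human_table, ecoli_table),
            fully_optimize(gene, ecoli_table),
            random_control(gene, ecoli_table, seed=seed),
        ):
            assert verify_synonymy(gene, res.output_sequence)

    @pytest.mark.parametrize("mode", ["relative_to_native", "absolute_floor"])
    def test_choices_match_bruteforce_oracle(
        self, mode, human_table, ecoli_table, random_gene_factory
    ):
        gene = random_gene_factory(seed=7, length=150)
        cfg = HarmonizationConfig(threshold=0.05, threshold_mode=mode)
        res = dumb_optimize(gene, human_table, ecoli_table, cfg)
        for rec in res.records:
            if rec.amino_acid == "*":
                continue
            expected = brute_force_codon_choice(
                rec.native_codon, human_table, ecoli_table, 0.05, mode
            )
            assert rec.chosen_codon == expected

    def test_fo_fraction_dominates_do_fraction(
        self, human_table, ecoli_table, random_gene_factory
    ):
        gene = random_gene_factory(seed=8, length=150)
        do = dumb_optimize(gene, human_table, ecoli_table).records
        fo = fully_optimize(gene, ecoli_table).records
        for rd, rf in zip(do, fo):
            assert rf.host_rel_fraction >= rd.host_rel_fraction - 1e-12

    def test_match_error_monotone_in_threshold(
        self, human_table, ecoli_table, random_gene_factory
    ):
        # default relative mode: raising τ can only worsen the total match
        gene = random_gene_factory(seed=9, length=100)
        totals = []
        for tau in np.linspace(0.0, 1.0, 11):
            cfg = HarmonizationConfig(threshold=float(tau))
            totals.append(dumb_optimize(gene, human_table, ecoli_table, cfg).total_match_error)
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_byte_identical_determinism(
        self, human_table, ecoli_table, random_gene_factory
    ):
        gene = random_gene_factory(seed=10, length=90)
        r1 = dumb_optimize(gene, human_table, ecoli_table)
        r2 = dumb_optimize(gene, human_table, ecoli_table)
        assert r1.output_sequence == r2.output_sequence
        assert r1.to_frame().equals(r2.to_frame())
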