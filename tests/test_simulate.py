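"""Synthetic read generator: reference construction, the RT-event model and
cohort assembly."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from rtsig import (
    DEFAULT_PARAMS,
    CohortConfig,
    SampleSpec,
    SignatureParams,
    expected_signature,
    make_reference,
    simulate_cohort,
    simulate_molecule,
    simulate_sample,
    simulate_signature_counts,
    site_base_distribution,
)
from rtsig.simulate import build_sample_specs


def _spec(**kw) -> SampleSpec:
    base = dict(sample_id="s1", group="case", braak=5, snp_carrier=False,
                theta=0.5, n_molecules=100, seed=7)
    base.update(kw)
    return SampleSpec(**base)


class TestMakeReference:
    def test_codon_context_and_snp_allele(self, amplicon):
        s = amplicon.site_local
        assert amplicon.seq[s - 3 : s] == "GCA"
        assert amplicon.site.genome_pos - amplicon.snp.genome_pos == 2
        assert amplicon.seq[amplicon.snp_local - 1] == amplicon.snp.ref_allele

    def test_deterministic(self):
        assert make_reference(seed=3).seq == make_reference(seed=3).seq
        assert make_reference(seed=3).seq != make_reference(seed=4).seq

    def test_no_homopolymer_of_three(self):
        for seed in range(5):
            seq = make_reference(seed=seed).seq
            assert not any(
                seq[i] == seq[i + 1] == seq[i + 2] for i in range(len(seq) - 2)
            )

    def test_genome_anchoring(self, amplicon):
        assert amplicon.local_pos(amplicon.site.genome_pos) == amplicon.site_local
        assert amplicon.snp_local == amplicon.site_local - 2

    @pytest.mark.parametrize("length", [10, 59])
    def test_too_short_rejected(self, length):
        with pytest.raises(ValueError):
            make_reference(length=length)


class TestSignatureParams:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SignatureParams(p_readthrough=0.9)  # 0.9 + 0.17 + 0.02 + 0.01 != 1

    def test_t_is_not_a_misincorporation_key(self):
        with pytest.raises(ValueError):
            SignatureParams(p_readthrough=0.80, p_mis={"A": 0.1, "T": 0.07},
                            p_jump=0.02, p_arrest=0.01)

    def test_seq_error_bounds(self):
        with pytest.raises(ValueError):
            DEFAULT_PARAMS.with_(seq_error=0.5)


class TestSimulateMolecule:
    def test_unmodified_is_reference(self, amplicon, params_noerr, rng):
        read, ref_start, event = simulate_molecule(
            amplicon.seq, amplicon.site_local, params_noerr, False, rng
        )
        assert (read, ref_start, event) == (amplicon.seq, 1, "unmodified")

    @pytest.mark.parametrize(
        "event, sense_base",
        [("mis_A", "T"), ("mis_C", "G"), ("mis_G", "C"), ("readthrough", "A")],
    )
    def test_incorporation_shows_as_sense_complement(
        self, amplicon, params_noerr, rng, event, sense_base
    ):
        read, _, _ = simulate_molecule(
            amplicon.seq, amplicon.site_local, params_noerr, True, rng,
            force_event=event,
        )
        s = amplicon.site_local - 1
        assert read[s] == sense_base
        assert read[:s] == amplicon.seq[:s] and read[s + 1 :] == amplicon.seq[s + 1 :]

    def test_jump_deletes_the_site_base(self, amplicon, params_noerr, rng):
        read, ref_start, _ = simulate_molecule(
            amplicon.seq, amplicon.site_local, params_noerr, True, rng,
            force_event="jump",
        )
        s = amplicon.site_local - 1
        assert ref_start == 1
        assert read == amplicon.seq[:s] + amplicon.seq[s + 1 :]

    def test_arrest_covers_only_downstream_of_site(self, amplicon, params_noerr, rng):
        read, ref_start, _ = simulate_molecule(
            amplicon.seq, amplicon.site_local, params_noerr, True, rng,
            force_event="arrest",
        )
        assert ref_start == amplicon.site_local + 1
        assert read == amplicon.seq[amplicon.site_local :]


class TestSimulateSample:
    def test_theta_zero_no_error_reproduces_reference(self, amplicon, params_noerr):
        reads, truth = simulate_sample(
            _spec(theta=0.0, n_molecules=50), amplicon, params_noerr
        )
        assert all(seq == amplicon.seq for _, seq in reads)
        assert truth.counts["unmodified"] == 50

    def test_snp_carrier_has_no_site_signal_and_full_alt_allele(
        self, amplicon, params_noerr
    ):
        reads, truth = simulate_sample(
            _spec(snp_carrier=True, theta=0.5, n_molecules=200), amplicon, params_noerr
        )
        s, v = amplicon.site_local - 1, amplicon.snp_local - 1
        assert all(seq[s] == "A" for _, seq in reads)          # no mismatch at all
        assert all(seq[v] == amplicon.snp.alt_allele for _, seq in reads)
        assert truth.counts["unmodified"] == 200

    def test_degenerate_all_jump(self, amplicon, params_noerr):
        params = params_noerr.with_(p_readthrough=0.0, p_mis={}, p_jump=1.0,
                                    p_arrest=0.0)
        reads, truth = simulate_sample(
            _spec(theta=1.0, n_molecules=50), amplicon, params
        )
        assert truth.counts["jump"] == 50
        assert all(len(seq) == len(amplicon.seq) - 1 for _, seq in reads)

    def test_truth_counts_reconcile(self, amplicon):
        _, truth = simulate_sample(_spec(n_molecules=300), amplicon, DEFAULT_PARAMS)
        assert sum(truth.counts.values()) == 300

    def test_event_frequencies_concentrate(self, amplicon, params_noerr):
        n = 10_000
        _, truth = simulate_sample(
            _spec(theta=1.0, n_molecules=n, seed=11), amplicon, params_noerr
        )
        programmed = {
            "readthrough": params_noerr.p_readthrough,
            "mis_A": params_noerr.p_mis["A"],
            "mis_C": params_noerr.p_mis["C"],
            "mis_G": params_noerr.p_mis["G"],
            "jump": params_noerr.p_jump,
            "arrest": params_noerr.p_arrest,
        }
        for event, p in programmed.items():
            tol = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(truth.counts[event] / n - p) <= tol, event


class TestClosedForm:
    def test_site_distribution_sums_to_one(self):
        for theta in (0.0, 0.3, 1.0):
            d = site_base_distribution(theta, DEFAULT_PARAMS)
            assert abs(sum(d.values()) - 1.0) < 1e-12

    def test_simulator_matches_closed_form_mismatch_rate(self, amplicon):
        """Read-level mismatch/jump frequencies agree with the model's closed
        form, sequencing error included (the 2/3-style correction for errors
        that revert a misincorporated base is part of the distribution)."""
        theta, n = 0.5, 8000
        params = DEFAULT_PARAMS.with_(seq_error=0.002)
        reads, _ = simulate_sample(
            _spec(theta=theta, n_molecules=n, seed=21), amplicon, params
        )
        s = amplicon.site_local - 1
        L = len(amplicon.seq)
        base_calls = [seq[s] for _, seq in reads if len(seq) == L]
        n_jump = sum(1 for _, seq in reads if len(seq) == L - 1)
        exp = expected_signature(theta, params)
        mismatch = sum(1 for b in base_calls if b != "A") / len(base_calls)
        tol = 4 * np.sqrt(exp["mismatch_rate"] * (1 - exp["mismatch_rate"]) / len(base_calls))
        assert abs(mismatch - exp["mismatch_rate"]) <= tol
        jump = n_jump / (n_jump + len(base_calls))
        tol_j = 4 * np.sqrt(exp["jump_rate"] * (1 - exp["jump_rate"]) / n)
        assert abs(jump - exp["jump_rate"]) <= tol_j

    def test_count_level_simulator_matches_closed_form(self, rng):
        from rtsig import signature_from_pileup

        theta, n = 0.4, 50_000
        pile = simulate_signature_counts(theta, DEFAULT_PARAMS, n, rng)
        sig = signature_from_pileup(pile)
        exp = expected_signature(theta, DEFAULT_PARAMS)
        assert abs(sig.mismatch_rate - exp["mismatch_rate"]) <= 4 * np.sqrt(
            exp["mismatch_rate"] / n
        )
        assert abs(sig.jump_rate - exp["jump_rate"]) <= 4 * np.sqrt(
            exp["jump_rate"] / n
        )


class TestCohort:
    def test_cohort_shape_and_carrier_labels(self, tmp_path):
        cfg = CohortConfig(n_control=12, n_case=13, n_snp_carriers_case=2,
                           n_molecules=10, master_seed=5)
        _, metadata, truth = simulate_cohort(cfg, tmp_path / "c")
        assert len(list((tmp_path / "c").glob("*.fastq"))) == 25
        assert len(metadata) == 25
        assert metadata["group"].value_counts().to_dict() == {"case": 13, "control": 12}
        assert truth["snp_carrier"].sum() == 2
        assert truth.loc[truth.snp_carrier, "sample_id"].str.startswith("ad").all()

    def test_braak_ranges_by_group(self, tmp_path):
        cfg = CohortConfig(n_molecules=5, master_seed=2)
        _, metadata, _ = simulate_cohort(cfg, tmp_path / "c")
        ctl = metadata[metadata.group == "control"]["braak"]
        case = metadata[metadata.group == "case"]["braak"]
        assert ctl.between(0, 4).all()
        assert case.between(4, 6).all()

    def test_master_seed_reproducibility_is_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_control=3, n_case=3, n_snp_carriers_case=1,
                           n_molecules=40, master_seed=9)
        simulate_cohort(cfg, tmp_path / "a")
        simulate_cohort(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert ha == hb, name

    def test_different_seeds_differ(self, tmp_path):
        cfg1 = CohortConfig(n_control=2, n_case=2, n_snp_carriers_case=0,
                            n_molecules=30, master_seed=1)
        cfg2 = CohortConfig(n_control=2, n_case=2, n_snp_carriers_case=0,
                            n_molecules=30, master_seed=2)
        simulate_cohort(cfg1, tmp_path / "a")
        simulate_cohort(cfg2, tmp_path / "b")
        assert (tmp_path / "a" / "ctl01.fastq").read_bytes() != (
            tmp_path / "b" / "ctl01.fastq"
        ).read_bytes()

    def test_duplicate_sample_id_rejected(self, tmp_path):
        cfg = CohortConfig(n_control=1, n_case=1, n_snp_carriers_case=0,
                           n_molecules=5)
        dup = [_spec(sample_id="x", n_molecules=5),
               _spec(sample_id="x", n_molecules=5, group="control", braak=2)]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(cfg, tmp_path / "c", specs=dup)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            _spec(braak=7)
        with pytest.raises(ValueError):
            _spec(theta=1.5)
        with pytest.raises(ValueError):
            CohortConfig(n_case=1, n_snp_carriers_case=2)

    def test_snp_carrier_effective_theta_is_zero(self):
        assert _spec(snp_carrier=True, theta=0.5).effective_theta == 0.0

    def test_derived_seeds_are_stable(self):
        cfg = CohortConfig(master_seed=42)
        s1 = build_sample_specs(cfg)
        s2 = build_sample_specs(cfg)
        assert [s.seed for s in s1] == [s.seed for s in s2]
        assert all(0 <= s.seed < 2**31 for s in s1)
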