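"""The synthetic-data generator: fixture geometry, standards arithmetic,
read and qPCR simulators."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from blockamp import (
    QpcrSimConfig,
    ReadSimConfig,
    build_dilution_series,
    build_fixture_templates,
    default_signature,
    fit_ct_vs_logcopies,
    mix_standards,
    simulate_dilution_run,
    simulate_qpcr,
    simulate_qpcr_screen,
    simulate_reads,
    tally,
)
from blockamp.qpcr_calls import MeltWindow, call_sample, classify_specific
from blockamp.synthetic_data import (
    AmpliconTemplate,
    standard_mu,
    standard_nc1,
    standard_nc2,
    standard_wt,
)


def test_templates_differ_only_at_snv(templates):
    for t in templates:
        assert len(t.wt_seq) == len(t.mu_seq)
        diffs = [i for i, (a, b) in enumerate(zip(t.wt_seq, t.mu_seq)) if a != b]
        assert diffs == [t.snv_offset]
        assert (t.wt_base, t.mut_base) == ("T", "A")


def test_nanopore_template_is_137bp_with_primer_ends(table1, nanopore_template):
    assert len(nanopore_template.wt_seq) == 137
    assert nanopore_template.wt_seq.startswith("CACCTCAGATATTTTTCTTCA")
    assert nanopore_template.wt_seq.endswith(
        reverse_complement("CAATTCTTACCATCCACAAA"))


def test_detection_template_contains_blocker_sites(detection_template):
    assert "CTAGCCACAGTGAAATCTCGA" in detection_template.wt_seq
    assert "CTAGCCACAGAGAAATCTCGA" in detection_template.mu_seq


@pytest.mark.parametrize("name,strand", [
    ("F1", "fwd"), ("F2", "fwd"), ("F3", "fwd"),
    ("R4", "rev"), ("R5", "rev"), ("R6", "rev"), ("R7", "rev"), ("R8", "rev"),
    ("BF1", "fwd"), ("BF2", "fwd"), ("BF3", "fwd"),
    ("BR1", "rev"), ("BR2", "rev"), ("BR3", "rev"),
])
def test_each_published_site_occurs_exactly_once(table1, detection_template,
                                                 name, strand):
    site = table1[name].bases if strand == "fwd" else \
        reverse_complement(table1[name].bases)
    assert detection_template.wt_seq.count(site) == 1


def test_template_invariant_enforced():
    with pytest.raises(ValueError, match="differ exactly"):
        AmpliconTemplate("bad", "ACGT", "ACGT", 2)
    with pytest.raises(ValueError, match="differ exactly"):
        AmpliconTemplate("bad", "ACGT", "TCGA", 1)


def test_default_signature_unique_and_centered(nanopore_template, signature):
    k = len(signature.wt_signature)
    assert k == 11
    assert nanopore_template.wt_seq.count(signature.wt_signature) == 1
    assert signature.mu_signature not in nanopore_template.wt_seq
    assert nanopore_template.mu_seq.count(signature.mu_signature) == 1
    assert signature.wt_signature not in nanopore_template.mu_seq
    assert signature.wt_signature[k // 2] == "T"
    assert signature.mu_signature[k // 2] == "A"


def test_signature_length_validation():
    with pytest.raises(ValueError):
        default_signature(10)
    with pytest.raises(ValueError, match="annealing"):
        default_signature(81)


def test_equal_mix_of_standards_gives_9000_mutant_copies():
    mix = mix_standards(standard_mu(), standard_wt(), 0.5)
    assert mix.mutant_copies_per_uL == 9000.0
    assert mix.wildtype_copies_per_uL == 9000.0
    assert mix.carrier_ng_per_uL == 50.0


def test_mixing_identities():
    mu = standard_mu()
    assert mix_standards(mu, mu, 0.5) == mu
    assert mix_standards(mu, standard_wt(), 0.0) == standard_wt()
    assert mix_standards(mu, standard_wt(), 1.0) == mu


def test_negative_controls_carry_no_target():
    for nc in (standard_nc1(), standard_nc2()):
        assert nc.mutant_copies_per_uL == 0
        assert nc.wildtype_copies_per_uL == 0
    assert standard_nc2().carrier_ng_per_uL == 0


def test_simulated_reads_deterministic(panel, nanopore_template):
    cfg = ReadSimConfig(n_reads=50, true_mu_fraction=0.3, seed=9)
    a = simulate_reads(nanopore_template, panel[0], cfg)
    b = simulate_reads(nanopore_template, panel[0], cfg)
    assert a == b
    c = simulate_reads(nanopore_template, panel[0],
                       ReadSimConfig(n_reads=50, true_mu_fraction=0.3, seed=10))
    assert a != c


def test_error_free_reads_fully_classified(panel, signature, nanopore_template):
    cfg = ReadSimConfig(n_reads=1000, true_mu_fraction=0.0, sub_rate=0,
                        ins_rate=0, del_rate=0, seed=1)
    reads = [s for _, s, _ in simulate_reads(nanopore_template, panel[0], cfg)]
    result = tally(reads, panel, signature)
    bc1 = result["BC1"]
    assert (bc1.n_wt, bc1.n_mu, bc1.ratio_percent) == (1000, 0, 0.0)
    assert result.n_unassigned == result.n_multi_barcode == 0
    assert bc1.n_ambiguous == bc1.n_barcode_only == 0


def test_qpcr_highest_copy_standard_amplifies_near_cycle_30():
    cfg = QpcrSimConfig(seed=0, ct_noise_sd=0.0)
    recwin = simulate_qpcr("Mu", 9000, cfg)
    assert recwin.ct == pytest.approx(30.0, abs=0.5)
    assert classify_specific(recwin, MeltWindow())


def test_qpcr_no_template_no_amplification():
    cfg = QpcrSimConfig(seed=0, wt_breakthrough_prob=0.0)
    for label, copies in (("NC1", 0.0), ("NC2", 0.0), ("WT", 0.0), ("Mu", 0.0)):
        rec = simulate_qpcr(label, copies, cfg)
        assert rec.ct is None and rec.melt_peak_celsius is None


def test_qpcr_breakthrough_is_late_or_nonspecific():
    cfg = QpcrSimConfig(seed=2, wt_breakthrough_prob=1.0)
    rng = np.random.default_rng(2)
    for _ in range(200):
        rec = simulate_qpcr("WT", 0.0, cfg, rng=rng)
        assert rec.ct is not None
        late = rec.ct > 60.0
        nonspecific = not classify_specific(rec, MeltWindow())
        assert late or nonspecific


def test_simulated_dilution_series_fits_log_linear():
    series = build_dilution_series(9000, 3, 6)
    for seed in range(20):
        pts = simulate_dilution_run(series, QpcrSimConfig(seed=seed))
        slope, _, r = fit_ct_vs_logcopies(pts)
        assert abs(r) > 0.98
        assert slope == pytest.approx(-3.32, abs=0.5)


def test_screen_mu_positive_controls_negative():
    screen = simulate_qpcr_screen(QpcrSimConfig(seed=4), replicates=3)
    assert call_sample(screen["Mu"], ct_cutoff=45).call == "positive"
    for label in ("WT", "NC1", "NC2"):
        assert call_sample(screen[label], ct_cutoff=45).call == "negative"
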