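import numpy as np
import pytest

from barnaslip.genome_io import reverse_complement
from barnaslip.read_walker import (
    Read,
    ReadSet,
    WalkParams,
    coverage_stats,
    extend_both,
    extend_terminus,
    load_reads,
)
from barnaslip.synthetic_data import (
    GenomeConfig,
    apply_lesions,
    generate_genome,
    simulate_reads,
)


def _tiling_reads(seq: str, read_len: int = 50, step: int = 10) -> ReadSet:
    reads = [
        Read(id=f"t{i}", seq=seq[i : i + read_len])
        for i in range(0, len(seq) - read_len + 1, step)
    ]
    return ReadSet(reads=reads, source="tiling")


@pytest.fixture(scope="module")
def truth_seq():
    return generate_genome(GenomeConfig.small(), seed=9).genome.seq[:500]


#: error-free tiling covers the outermost columns exactly once, so full
#: terminus recovery needs a support threshold of one read
EXACT = WalkParams(min_support=1)


def test_exact_tiling_recovers_full_sequence(truth_seq):
    contig = truth_seq[:200]
    reads = _tiling_reads(truth_seq)
    result = extend_terminus(contig, reads, "three_prime", EXACT)
    assert result.final_seq == truth_seq
    assert result.added_3prime == 300
    assert result.added_5prime == 0


def test_five_prime_extension_mirrors_three_prime(truth_seq):
    contig = truth_seq[300:]
    reads = _tiling_reads(truth_seq)
    result = extend_terminus(contig, reads, "five_prime", EXACT)
    assert result.final_seq == truth_seq
    assert result.added_5prime == 300


def test_empty_readset_extends_nothing(truth_seq):
    contig = truth_seq[:100]
    result = extend_terminus(contig, ReadSet(reads=[]), "three_prime")
    assert result.final_seq == contig
    assert (result.added_5prime, result.added_3prime, result.reads_used) == (0, 0, 0)


def test_contig_always_substring_of_result(truth_seq):
    contig = truth_seq[100:300]
    reads = _tiling_reads(truth_seq)
    result = extend_both(contig, reads)
    assert contig in result.final_seq
    assert len(result.depth) == len(result.final_seq)


def test_reverse_complementing_all_reads_changes_nothing(truth_seq):
    contig = truth_seq[:200]
    reads = _tiling_reads(truth_seq)
    flipped = ReadSet(
        reads=[Read(id=r.id, seq=reverse_complement(r.seq)) for r in reads.reads]
    )
    a = extend_terminus(contig, reads, "three_prime")
    b = extend_terminus(contig, flipped, "three_prime")
    assert a.final_seq == b.final_seq
    assert a.reads_used == b.reads_used


def test_deterministic_given_fixed_inputs(truth_seq):
    contig = truth_seq[:200]
    reads = _tiling_reads(truth_seq)
    r1 = extend_terminus(contig, reads, "three_prime")
    r2 = extend_terminus(contig, reads, "three_prime")
    assert r1.final_seq == r2.final_seq


def test_interior_depth_of_exact_tiling_is_combinatorial(truth_seq):
    """50-mers every 10 nt cover each interior position 50/10 = 5 times."""
    reads = _tiling_reads(truth_seq)
    stats = coverage_stats(truth_seq, reads)
    interior = stats.depth[60:-60]
    assert int(np.median(interior)) == 5
    assert stats.reads_used == len(reads.reads)


def test_no_matching_reads_gives_zero_stats(truth_seq):
    other = "ACGU" * 30
    stats = coverage_stats(other, _tiling_reads(truth_seq))
    assert (stats.reads_used, stats.mean_depth, stats.min_depth,
            stats.max_depth) == (0, 0.0, 0, 0)


def test_simulated_mean_depth_within_three_standard_errors():
    bundle = generate_genome(GenomeConfig(), seed=4)
    depth = 19.0
    reads = simulate_reads(bundle.genome, depth, 100, 0.0, seed=11)
    stats = coverage_stats(bundle.genome.seq, reads)
    interior = stats.depth[100:-100]
    se = np.sqrt(depth) / np.sqrt(len(interior) / 100)  # ~independent windows
    assert abs(interior.mean() - depth) < 3 * se + 0.5


def test_truncated_genome_recovery_with_errors():
    """Termini truncated by 879 and 31 nt are walked back from 1%-error reads."""
    bundle = generate_genome(GenomeConfig(), seed=6)
    lesioned = apply_lesions(bundle, truncations=(879, 31))
    reads = simulate_reads(bundle.genome, 20, 100, 0.01, seed=66)
    result = extend_both(lesioned.genome.seq, reads)
    assert result.added_5prime <= 879 and result.added_3prime <= 31
    recovered = result.added_5prime + result.added_3prime
    assert recovered >= 0.9 * 910
    truth = bundle.genome.seq
    span = truth[879 - result.added_5prime : len(truth) - 31 + result.added_3prime]
    mismatches = sum(1 for x, y in zip(span, result.final_seq) if x != y)
    assert mismatches / max(recovered, 1) < 0.01


def test_load_reads_fastq_and_fasta(tmp_path):
    fq = tmp_path / "r.fastq"
    fq.write_text("@r1\nACGT\n+\nIIII\n")
    rs = load_reads(fq)
    assert rs.reads[0].seq == "ACGU"
    assert rs.reads[0].quality == "IIII"
    fa = tmp_path / "r.fasta"
    fa.write_text(">r1\nacgt\n")
    assert load_reads(fa).reads[0].seq == "ACGU"


def test_short_reads_are_skipped_not_fatal(truth_seq):
    reads = ReadSet(reads=[Read(id="s", seq="ACGU")])
    assert reads.usable(21) == []
    result = extend_terminus(truth_seq[:100], reads, "three_prime")
    assert result.added_3prime == 0
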