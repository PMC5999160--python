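"""Generate a barnavirus-like genome and annotate its ORF architecture.

The generator plants the canonical four-ORF layout; the annotator must
recover it blind: ORF2 from its first AUG, ORF3 from its bracketing stops,
and the -1-frame relationships between them.
"""

from barnaslip.orf_annotator import annotate, overlap_region, upstream_inframe_stop
from barnaslip.synthetic_data import GenomeConfig, generate_genome

bundle = generate_genome(GenomeConfig(), seed=1)
genome = bundle.genome
print(f"genome {genome.id}: {len(genome)} nt")

arch = annotate(genome)
for name in ("ORF1", "ORF2", "ORF3", "ORF4"):
    orf = arch.get(name)
    print(
        f"  {name}: {orf.interval.start:>5}..{orf.interval.end:<5} "
        f"frame {orf.frame}  {orf.protein_length:>4} aa  ({orf.rule})"
    )

ov = overlap_region(arch.get("ORF2"), arch.get("ORF3"))
print(f"ORF2/ORF3 overlap between stop codons: {ov.start}..{ov.end} "
      f"({len(ov)} nt, ORF3 in the -1 frame)")
print(f"in-frame stop {upstream_inframe_stop(genome, arch.get('ORF2'))} codons "
      f"upstream of ORF2's AUG -> ORF2 cannot initiate further 5'")
# The overlap length and frame offsets are the architecture signature that
# identifies a barnavirus-like genome organisation.
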