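"""Paired-end reads and purity mixing.

Simulates reads from a normal and a tumor genome, mixes them at 80%
purity, and recovers the purity from the provenance-encoding read names.
"""

from svforge import generate_synthetic_reference
from svforge.genome import HaplotypeSet
from svforge.reads import MixtureSpec, ReadConfig, mix_reads, simulate_read_pairs

reference = generate_synthetic_reference({"chr1": 200_000}, gc_target=0.41, seed=8)
seq = reference.chromosomes["chr1"]
normal = HaplotypeSet([("chr1", 0, seq), ("chr1", 1, seq)], "normal")
tumor = HaplotypeSet([("chr1", 0, seq), ("chr1", 1, seq)], "tumor")

config = ReadConfig(read_length=100, coverage=10.0,
                    insert_mean=320.0, insert_sd=60.0, error_rate=0.001)
streams = {
    "normal": simulate_read_pairs(normal, config, seed=9, n_pairs=12_000),
    "tumor": simulate_read_pairs(tumor, config, seed=10, n_pairs=45_000),
}
n = 50_000
mixed = mix_reads(streams, MixtureSpec({"normal": 0.2, "tumor": 0.8}), n, seed=11)
tumor_frac = sum(p.provenance.genome_id == "tumor" for p in mixed) / n
example = mixed[0]
print(f"requested purity 0.8, realized tumor fraction {tumor_frac:.4f}")
print(f"first read name: {example.name}")
# The name encodes genome|chromosome|haplotype|S1|S2|strand|serial, so the
# fragment's donor segment (S1..S2+r) can always be recovered exactly.
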