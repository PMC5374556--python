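"""Independent left-to-right rebuild oracle for variant application.

Rebuilds each haplotype by walking the reference from position 0,
emitting unchanged reference segments and event payloads in order —
a completely different route from the production backward application.
"""

from svforge.genome import ReferenceGenome, reverse_complement
from svforge.variants import VariantPlan


def _on_hap(hap, haplotype) -> bool:
    return hap is None or hap == haplotype


def rebuild_haplotype(
    reference: ReferenceGenome, plan: VariantPlan, chrom: str, haplotype: int
) -> str:
    refseq = reference.chromosomes[chrom]
    ops: list[tuple[int, int, str]] = []
    for v in plan.snvs:
        if v.chromosome == chrom and _on_hap(v.haplotype, haplotype):
            ops.append((v.position, v.position + 1, v.alt))
    for v in plan.indels:
        if v.chromosome == chrom and _on_hap(v.haplotype, haplotype):
            ops.append((v.position, v.position + len(v.ref), v.alt))
    for ev in plan.svs:
        seg = reference.chromosomes[ev.chromosome][ev.start:ev.end]
        here = ev.chromosome == chrom
        mine = _on_hap(ev.haplotype, haplotype)
        if ev.sv_class == "deletion" and here and mine:
            ops.append((ev.start, ev.end, ""))
        elif ev.sv_class == "insertion" and here and mine:
            ops.append((ev.start, ev.start, ev.inserted_seq))
        elif ev.sv_class == "inversion" and here and mine:
            ops.append((ev.start, ev.end, reverse_complement(seg)))
        elif ev.sv_class == "tandem_duplication" and here and mine:
            ops.append((ev.start, ev.end, seg * (1 + ev.extra_copies)))
        elif ev.sv_class in ("intra_translocation", "inter_translocation"):
            if ev.balanced and here and mine:
                ops.append((ev.start, ev.end, ""))
            if ev.dest_chromosome == chrom and mine:
                ops.append((ev.dest_position, ev.dest_position, seg))
        elif ev.sv_class == "cnv" and here:
            cn = ev.copy_number
            if cn == 0 or (cn == 1 and mine):
                ops.append((ev.start, ev.end, ""))
            elif cn > 2 and mine:
                for d in ev.dest_positions:
                    ops.append((d, d, seg))
    ops.sort()
    parts: list[str] = []
    cursor = 0
    for start, end, text in ops:
        assert start >= cursor, "oracle requires non-overlapping operations"
        parts.append(refseq[cursor:start])
        parts.append(text)
        cursor = end
    parts.append(refseq[cursor:])
    return "".join(parts)


def expected_length_delta(plan: VariantPlan, reference, chrom, haplotype) -> int:
    """Net length change of one haplotype, from first principles."""
    delta = 0
    for v in plan.indels:
        if v.chromosome == chrom and _on_hap(v.haplotype, haplotype):
            delta += len(v.alt) - len(v.ref)
    for ev in plan.svs:
        here = ev.chromosome == chrom
        mine = _on_hap(ev.haplotype, haplotype)
        if ev.sv_class == "deletion" and here and mine:
            delta -= ev.span
        elif ev.sv_class == "insertion" and here and mine:
            delta += len(ev.inserted_seq)
        elif ev.sv_class == "tandem_duplication" and here and mine:
            delta += ev.span * ev.extra_copies
        elif ev.sv_class in ("intra_translocation", "inter_translocation"):
            if ev.balanced and here and mine:
                delta -= ev.span
            if ev.dest_chromosome == chrom and mine:
                delta += ev.span
        elif ev.sv_class == "cnv" and here:
            cn = ev.copy_number
            if cn == 0 or (cn == 1 and mine):
                delta -= ev.span
            elif cn > 2 and mine:
                delta += ev.span * (cn - 2)
    return delta
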