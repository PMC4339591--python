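# cnmskit

Discovery of **conserved non-coding microsatellite (CNMS) markers** in
the 5' upstream regulatory regions of protein-coding genes.

Microsatellites (SSRs) that sit inside known cis-regulatory element /
transcription-factor-binding-site signal sequences, within segments
conserved across related species, make unusually informative genetic
markers: their repeat-length variation is easy to genotype as fragment
length polymorphism and plausibly functional, because it perturbs a
binding site that selection has retained. `cnmskit` is for crop and
plant genomicists who want to build such marker panels from upstream
FASTA sets, and provides the downstream survey arithmetic (PIC,
polymorphism percentages, linkage-map summaries) used to characterise
them.

A marker is called when three conditions hold on an upstream window
(default the 1000 bp ending at the ATG):

1. a perfect tandem repeat of a primitive 1–6 nt unit `u`, tract
   `(u)_n` with n·|u| ≥ 12 bp (class I ≥ 20 bp, class II 12–19 bp);
2. the tract intersects a match of an IUPAC signal consensus from an
   element library (e.g. GAGA8HVBKN3 = (GA)₈, RAV1AAT = CAACA), matched
   exact-degenerate on both strands;
3. the composite SSR∪signal interval is contained in an ungapped
   conserved block (length ≥ 20 bp, identity ≥ 0.70, 8-mer seed) shared
   with ≥ 1 orthologous/paralogous upstream region.

Each marker then gets flanking PCR primers (product 100–300 bp, primer
18–24 nt, GC 40–60 %, Tm 50–62 °C, unique in template, never
overlapping the tract), so an expansion by k repeat units shifts the
amplicon by exactly k·|u| bp. Marker informativeness uses
PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ² over allele frequencies pᵢ.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

Generate a seeded synthetic multi-species bundle (planted composites,
decoys, truth table) and run the full pipeline:

```python
from cnmskit import SimConfig, simulate_upstream_set, discover

bundle = simulate_upstream_set(SimConfig(seed=42))
res = discover(bundle.target, bundle.comparators,
               bundle.orthology, bundle.elements)
for m in res.markers:
    p = m.primer_pair
    print(m.marker_id, m.gene_id, m.motif, m.element_name,
          ",".join(m.supporting_species),
          f"{m.up_interval.start_up}-{m.up_interval.end_up}",
          p.fwd_seq, p.rev_seq, p.product_size)
```

prints

```
CNMS0001 g001 (GA)12 CTRMCAMV35S comp1 142-165 GCCTTGATACTGTGGAACATA GACGCCGGAAGATATTAAATC 200
CNMS0002 g001 (GA)12 GAGA8HVBKN3 comp1 142-165 GCCTTGATACTGTGGAACATA GACGCCGGAAGATATTAAATC 200
CNMS0003 g002 (TC)8 CTRMCAMV35S comp1,comp2 60-76 GGGTCAAGGGTAGTCCACT GACAGTTACTCGGTTCGAATT 200
CNMS0004 g002 (TC)8 GAGA8HVBKN3 comp1,comp2 61-76 GGGTCAAGGGTAGTCCACT GACAGTTACTCGGTTCGAATT 200
CNMS0005 g003 (CAA)7 RAV1AAT comp1,comp2,comp3 84-104 TTACAAACAATTCTACTCACGGCC CGCATTTTTGGGTCATACCG 200
CNMS0006 g004 (ATGGT)3 S1FBOXSORPS1L21 comp1 683-697 TGCACAGGTCATTTGTACTATC GCATCTGAAGATTCCACAAAATGC 200
```

Six markers: the four genes carrying planted composites each yield a
marker per matching element — a (GA)₁₂ or (TC)₈ tract satisfies both
the GAGA8HVBKN3 and (on the minus strand) the CTRMCAMV35S consensus,
hence two markers on g001/g002 — with their supporting comparator
species, ATG-relative position (e.g. 142–165 bp upstream of the start
codon), and a primer pair amplifying a 200-bp product. The three decoy
genes (SSR without element, element without SSR, unconserved composite)
yield nothing. Survey arithmetic works the same way from printed
counts:

```python
>>> from cnmskit import survey_percent, pic
>>> survey_percent(256, 631)   # polymorphic among amplified markers
40.6
>>> round(pic([0.25] * 4), 4)  # four equifrequent alleles
0.7031
```

The same pipeline is scriptable from the shell:

```sh
cnmskit simulate --seed 42 --out bundle/
cnmskit discover --target bundle/target.fa \
    --comparator comp1=bundle/comp1.fa --comparator comp2=bundle/comp2.fa \
    --comparator comp3=bundle/comp3.fa \
    --orthology bundle/orthology.tsv --elements bundle/elements.tsv \
    --outdir run/
```

which writes `markers.tsv`, `markers.gff3`, `histogram.tsv` (marker
counts per 100-bp upstream interval) and `report.txt`. Subcommands
`ssr`, `scan`, `cns`, `primers` and `stats` expose the individual
stages.

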