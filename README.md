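# polydup

Tools for cataloguing a highly duplicated gene family encoded as
**multi-unit polyproteins** — the situation found for light-harvesting
complex (LHC) antenna genes in dinoflagellates such as the coral symbiont
*Symbiodinium*, where a single gene model encodes several tandem
three-transmembrane-helix protein units that are cleaved apart after
translation.

Given protein gene models (FASTA) and a locus map (GFF3), the pipeline:

1. **decomposes** each polyprotein into single LHC-like units with a
   position-weight-matrix profile scan, collapsing same-locus redundant
   copies (alternative splice-form echoes);
2. **aligns** the units (progressive alignment on a UPGMA k-mer guide
   tree, affine-gap BLOSUM62 scoring) and trims gap-rich columns;
3. builds a **neighbor-joining tree** on Poisson-corrected p-distances
   with bootstrap supports (default 400 resamplings);
4. **classifies** every unit: subfamily (R-type vs F-type, anchored by
   reference sequences), phylogroup (maximal single-subfamily clades with
   support ≥ 0.9), and subgroup (maximal supported clades at ≥ 0.8 nested
   inside a group; label 0 = no affiliation);
5. calls each unit's **duplication mode** from its nearest homolog:
   *intragenic* (closest homolog in the same locus — a tandem copy),
   *intergenic* (closest homolog in a physically separate locus — a
   dispersed copy), or *ambiguous* on an exact two-sided tie;
6. detects **fusion loci** (one polyprotein carrying units of both
   subfamilies) and tests the association between a junction **cleavage
   motif** (default `SPLR`) and the most expanded F clade with a
   two-sided Fisher exact test computed by hypergeometric enumeration;
7. summarises expression as **RPKM** = count / (length/10³) / (total/10⁶)
   from externally produced read counts.

Because real genomes come without ground truth, the package ships a
forward **simulator** of the duplication process (tandem and dispersed
duplication, whole-locus copies, inter-subfamily fusion, gene conversion,
loss, per-site substitution) that emits FASTA/GFF3 plus a complete event
log, so every classification step is validated by parameter recovery.

## Worked example

Run the full pipeline on a simulated family (the default simulation:
two founder subfamilies at 40 % divergence, duplication rates
0.3/0.3 intragenic/intergenic, fusion 0.05, loss 0.05 per generation,
60 generations, 120-residue units):

```sh
$ polydup run --out rundir --seed 9
15 loci, 42 units, 5 fusion loci -> rundir/summary.json

$ polydup report --rundir rundir | head -4
L0002   F1.0|F1.0|F1.0|F1.0|F1.0|R1.1|R1.1
L0003   R1.0
L0004   R1.0
L0005   R1.0|R1.0|F1.0
```

Each report line is one locus with its units in genomic order, labelled
`<group>.<subgroup>`; `L0002` is a seven-unit fusion locus carrying five
F-type and two R-type units. `rundir/summary.json` holds the run's
headline numbers:

```
"n_loci": 15, "n_units_detected": 48, "n_units_nonredundant": 42,
"n_fusion_loci": 5,
"mode_counts": {"intragenic": 2, "intergenic": 32, "ambiguous": 8},
"motif_table": [[5, 2], [0, 8]], "motif_fisher_p": 0.00699
```

Here 48 scanned units collapse to 42 non-redundant ones; 5 of 15 loci are
fusion loci; and the junction cleavage motif occurs in 5 of the 7 loci
containing the most expanded F clade but in none of the other 8 loci
(Fisher exact p = 0.007) — the motif is confined to one lineage, as the
simulator planted it.

Every stage is also exposed separately (`polydup simulate / scan / align /
tree / classify / expr`), reading and writing plain FASTA, GFF3, Newick
and TSV so stages can be re-run or swapped individually.

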