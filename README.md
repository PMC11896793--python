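# oligotiler

Design of overlapping, alternating-strand oligomer sets for building long
double-stranded DNA by **polymerase chain assembly (PCA)**.

Gene synthesis from pooled oligomers fails in characteristic ways: junction
overlaps that melt at the wrong temperature, 3′ termini that misprime,
GC-clamped ends that stick where they should not, and repeated sequence that
lets an oligomer anneal at the wrong junction altogether (insertions,
deletions, scrambled assemblies).  `oligotiler` takes a target sequence and
splits it into an ordered set of oligomers — odd ordinals on the top strand,
even on the bottom, adjacent oligomers intersecting in an annealing overlap —
so that every junction is as unambiguous and thermodynamically uniform as the
sequence allows.  It is a library plus a small command-line tool, aimed at
anyone ordering oligo pools for PCA-based gene assembly.

## The penalty score

Every candidate oligomer is scored with an unweighted five-term penalty

```
score = |T_t − T_c| + 1_T + GC_clamp + R_within + R_between
```

| term | meaning |
|---|---|
| `\|T_t − T_c\|` | deviation of the overlap's calculated melting temperature `T_c` from the user's target `T_t` (°C) |
| `1_T` | 1 if the oligomer's own-strand 3′-terminal base is thymine (a weakly pairing, misprime-prone terminus), else 0 |
| `GC_clamp` | G/C count above 3 in the terminal five bases of the annealing overlap |
| `R_within` | base pairs of the oligomer covered by a repeated k-mer (default k = 8), counting a k-mer and its reverse complement as the same key |
| `R_between` | base pairs its overlap shares (canonical k-mers, default k = 10) with non-adjacent overlaps |

A theoretically faultless oligomer scores 0.  `T_c` comes from the unified
nearest-neighbor thermodynamic parameter set (two-state model, `C_T/4`
concentration factor, `16.6·log₁₀[Na⁺]` salt correction).  The designer walks
the target left to right, enumerates every admissible (oligomer length,
overlap length) pair at each step, prefers candidates whose overlap GC content
lies in 40–60%, and takes the minimum-penalty candidate — falling back to the
next-best fit when nothing is ideal, never failing outright.  Afterwards,
consecutive oligomers are segregated into sub-pool clusters so that no two
non-adjacent overlaps within a cluster share a canonical 10-mer, and an
in-silico verification reconstructs the target from the oligomer set.

## Worked example

Design a synthetic 520 bp GC-balanced target (the fixtures module generates
it deterministically) with the classic worked-example settings — oligomers up
to 50 nt, overlaps 15–20 bp, target overlap Tm 56 °C:

```
$ python -c "
from oligotiler import fixtures, write_fasta
write_fasta([fixtures.gc_balanced(520, 2, name='demo')], 'demo.fa')"
$ oligotiler design --input demo.fa --out-prefix demo --target-tm 56
demo: 20 oligomers, 1 cluster(s) -> demo.oligos.csv
```

The 520 bp target is covered by 20 oligomers in a single assembly pool.
`demo.oligos.csv` is the order sheet — every sequence written 5′→3′ on its
own strand, with its overlap, overlap Tm/GC and score breakdown:

```
index,name,strand,ref_start,ref_end,length,sequence,overlap_with_next,overlap_tm,overlap_gc,tm_dev,three_prime_t,gc_clamp,r_within,r_between,total,cluster
1,demo_oligo_001,top,1,50,50,GTGTACTGAGTTAGCCCAATTCTATATTCCTATAATGCTGGGAACCAGGT,ATAATGCTGGGAACCAGGT,51.46,47.37,4.54,1,0,0,0,5.54,1
2,demo_oligo_002,bottom,32,81,50,CGTAGGGTATACGTCCATGTTTCATAGGTGGACCTGGTTCCCAGCATTAT,ACATGGACGTATACCCTACG,51.22,50.00,4.78,1,0,0,0,5.78,1
3,demo_oligo_003,top,62,109,48,ACATGGACGTATACCCTACGTTACCTGCTCATGCACCCGGTTTAGTCA,TCATGCACCCGGTTTAGTCA,54.54,50.00,1.46,0,0,0,0,1.46,1
```

Row 1 reads: the first (top-strand) oligomer spans reference positions 1–50,
its 19 bp overlap with oligomer 2 melts at 51.46 °C (4.54 °C below the 56 °C
target) and it ends in T, so its penalty is 4.54 + 1 = 5.54.  `demo.report.txt`
flags such oligomers (`TM` = overlap Tm outside the ±2.5 °C tolerance) as
candidates for re-design, and `demo.layout.txt` draws the tiling:

```
5' GTGTACTGAGTTAGCCCAATTCTATATTCCTATAATGCTGGGAACCAGGTCCACCTATGAAACATGG...
5'-GTGTACTGAGTTAGCCCAATTCTATATTCCTATAATGCTGGGAACCAGGT-3'  [1]
                               3'-TATTACGACCCTTGGTCCAGGTGGATACTTTGTACC...
```

Verify a design against its reference, or re-design from a chosen oligomer
onward with different knobs (earlier oligomers are kept byte-identical):

```
$ oligotiler verify --design demo.oligos.csv --reference demo.fa
$ oligotiler optimize --design demo.oligos.csv --index 6 --out demo2.csv --max-overlap-len 18
```

To run the example on the real 520 bp M13 bacteriophage fragment instead of a
synthetic target, fetch it once with `python scripts/fetch_m13.py` (needs
network) and point `--input` at the downloaded FASTA.

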