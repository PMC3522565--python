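# phylofoot

Phylogenetic footprinting of orthologous promoter sets.

`phylofoot` compares the cis-regulatory information content of promoters of
orthologous genes across species — the setting is a set of clusters of
orthologous genes (COGs, e.g. one rice, one sorghum and one Arabidopsis
copy of a stress-associated bZIP transcription factor, plus non-orthologous
paralogs as a negative contrast).  It answers three questions:

1. **Which transcription-factor binding site (TFBS) classes occur in each
   promoter?**  The −1000..+200 window around each transcription start site
   is scanned against a library of 6–8 nt position weight matrices (PWMs)
   with conservation-weighted similarity scores, and occurrences are
   binarized into a TFBS-class × gene matrix.
2. **How is each TFBS class conserved?**  Classes are partitioned into
   mutually exclusive conservation categories: shared by orthologs *and*
   paralogs (I), ortholog-specific (II), lineage-specific (III, e.g. both
   monocots but not the dicot), species-specific (IV), and paralog-specific
   (P).
3. **Which classes form spatially conserved "core modules"?**  Ordered
   combinations of 2–4 classes whose order, strand orientation and
   inter-site spacing recur in *every* ortholog promoter while no
   equivalent arrangement exists in any paralog.

Per-species class counts are compared by Pearson chi-square tests against
equal ratios (1:1:1 / 1:1), and binary occurrence matrices are clustered
hierarchically (Jaccard distance, average linkage, deterministic
tie-breaking) to expose species- and lineage-level similarity patterns.

## The scores

For a PWM with per-position frequencies *f(i, b)* the conservation weight
of position *i* is

    ci(i) = (100 / ln 4) · (ln 4 + Σ_b f(i,b) ln f(i,b))

(0 for an uninformative position, 100 for an invariant one).  A window
*s₁…s_L* scores

    mat_sim = Σ_i ci(i) f(i, s_i)  /  Σ_i ci(i) max_b f(i, b)

and `core_sim` is the same ratio over the contiguous 4 positions of
maximal summed conservation.  A hit must pass both thresholds (defaults
0.75 / 0.85, overridable per matrix by "optimized" thresholds in the
library file).  Significance is exact: the probability that a random
background window passes both thresholds is computed by dynamic
programming (no sampling), and each hit reports the implied expected
chance-hit count in its promoter as an e-value.  The significance cutoff
(default 10⁻³) is applied to the per-site probability — see
`docs/methods.md` for why that is the only scale on which a 10⁻³ cutoff
is attainable for 6–8 nt motifs.

Because the proprietary plant PWM collections used in this research area
cannot be redistributed, the package ships a synthetic 26-class library
(plant-style class mnemonics, generated pairwise-dissimilar consensi) and
a seeded promoter simulator that plants core modules and category-patterned
singleton sites into scrubbed background sequence, with a ground-truth
manifest for end-to-end validation.

## Worked example

```python
import phylofoot as pf

# a synthetic COG: 3 orthologs (Os/Sb monocot, At dicot) + 2 paralogs,
# with one planted 2-class module and singleton classes in categories I-IV/P
ds = pf.simulate_cog_dataset(pf.example_design(seed=7, n_cogs=1))

hits = pf.scan_promoters(ds.library, ds.promoters, background=(0.25,) * 4)
occ = pf.build_occurrence_matrix(hits, ds.promoters, ds.library.class_map)
cogs = pf.cog_definitions_from_table(ds.cog_table)
reports = pf.classify_cogs(occ, cogs)
print(pf.summarize_counts(reports, occ, cogs).to_string())
```

```
                     C1
TFBS in all species   4
TFBS in At only       1
TFBS in Os only       1
TFBS in Sb only       1
```

Four classes occur in every species (the two module classes plus the
planted category-I and II singletons); each species carries one unique
(category IV) class.  The category map for the COG:

```python
{c: (a.category, a.detail) for c, a in sorted(reports["C1"].assignments.items())}
# {'ABRE': ('II', ''), 'AGP1': ('II', ''), 'AHBP': ('I', ''),
#  'BRRE': ('II', ''), 'CAAT': ('III', 'monocot'), 'CE1F': ('III', 'monocot'),
#  'CGCG': ('IV', 'Os'), 'CNAC': ('IV', 'Sb'), 'DOFF': ('IV', 'At'),
#  'EINL': ('P', '')}
```

Module detection recovers the planted arrangement in all three orthologs:

```python
by_gene = {}
for h in hits:
    by_gene.setdefault(h.gene_id, []).append(h)
cog = cogs[0]
mods = pf.detect_core_modules(
    {g: by_gene.get(g, []) for g in cog.ortholog_genes},
    {g: by_gene.get(g, []) for g in cog.paralogs}, cog_id=cog.cog_id)
print(pf.render_module_alignment(mods[0]))
```

```
module ABRE-AGP1 [+-] spacing 40 +/-10nt
C1_At    -698 ABRE(+) --40-- AGP1(-)
C1_Os    -455 ABRE(+) --40-- AGP1(-)
C1_Sb    -666 ABRE(+) --40-- AGP1(-)
```

The same two-class signature sits at different distances from the TSS in
each species (anchors −698/−455/−666) with identical 40-nt spacing — the
hallmark of a conserved core module.  Chi-square comparison of unique
class counts works on any count vector, e.g. 74/70/52-style per-species
counts:

```python
res = pf.chisq_equal_ratio([74, 70, 99])   # X² = 6.099, df = 2, p = 0.047 *
```

And the gene-axis dendrogram of the ortholog occurrence profiles puts the
two monocots together first:

```
(C1_At:0.25,(C1_Os:0.125,C1_Sb:0.125):0.125);
```

The whole analysis is also available as one command over a YAML config
(`phylofoot run --config cfg.yaml`) producing a diff-able bundle of
TSV/JSON/FASTA/Newick files with caching and checksums, or step by step
via the `extract`, `scan`, `classify`, `modules`, `stats` and `simulate`
verbs.

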