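"""Expression workflow: FPKM, replicate QC, clustering, DE, enrichment.

Simulates a 6-tissue x 3-replicate count matrix with 9 planted expression
archetypes and one deliberately corrupted (label-permuted) library, then
runs the analysis chain: low-expression filter -> log2(FPKM+1) ->
bootstrap replicate QC -> top-MAD gene selection -> correlation-distance
complete-linkage clustering cut at 9 -> a 3v3 differential-expression test
-> hypergeometric enrichment of the DE set against the planted clusters.
"""
from bambuseq import (
    CountDesign, apply_thresholds, bootstrap_replicate_qc,
    correlation_distance, de_test, enrich, filter_low, hcluster_cut,
    log2_fpkm, mad_select, simulate_counts,
)
from bambuseq.expression import subset

design = CountDesign(n_genes=2000, outlier_libraries=("Fl2_R2",))
cm, truth = simulate_counts(design, seed=3)

cm = filter_low(cm, min_mean=1)
em = log2_fpkm(cm)

qc = bootstrap_replicate_qc(em, truth.library_tissue, n_boot=500, seed=4)
print("flagged libraries:", qc.flagged)   # the planted outlier, and only it

top = mad_select(em, top_n=1500)
emt = subset(em, top)
cr = hcluster_cut(correlation_distance(emt.values, emt.genes), emt.genes, k=9)
sizes = {}
for lab in cr.assignments.values():
    sizes[lab] = sizes.get(lab, 0) + 1
print("cluster sizes:", dict(sorted(sizes.items())))

libs_a = [l for l in cm.libraries if l.startswith("Cb_")]
libs_b = [l for l in cm.libraries if l.startswith("Fl3_")]
de = de_test(cm, libs_a, libs_b)
called = apply_thresholds(de, p=0.01, fc=2)
print(f"DE genes (culm bud vs flower stage 3): {len(called)}")

# enrichment of the DE set against planted-archetype "terms"
idx = {g: i for i, g in enumerate(cm.genes)}
terms = {}
for g in cm.genes:
    terms.setdefault(f"cluster{truth.cluster_labels[idx[g]]}", []).append(g)
res = enrich(called, terms, cm.genes)
print(res[res["padj"] < 0.05][["k", "K", "p", "padj"]])
# Archetypes that differ between the two tissues surface as enriched terms.
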