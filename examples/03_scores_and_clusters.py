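"""Term-impact score matrices and the GLM dendrogram-cut rule.

Builds the two heatmap scores over the union of significant terms and
chooses the number of term clusters from the first dendrogram merge
whose height breaks above a Gaussian/log-link GLM fitted to the merge
heights.
"""

from seedgo import (
    SyntheticConfig,
    build_score_matrix,
    call_degs,
    choose_cluster_count,
    extract_ego_interactors,
    fit_glm_log_link,
    generate_study,
    hcluster_rows,
    intersect_deg_interactors,
    overrepresent,
)

study = generate_study(SyntheticConfig(rng_seed=3))
ia = extract_ego_interactors(study.interactome, "SEED", 0.4)
deg_sets, selected = {}, set()
for label, table in study.tables.items():
    dis = intersect_deg_interactors(call_degs(table), ia, table)
    deg_sets[label] = dis
    selected |= overrepresent(dis, study.annotations).significant_terms()
print(f"{len(selected)} terms significant in at least one comparison\n")

for kind in ("ratio", "fc_weighted"):
    sm = build_score_matrix(selected, deg_sets, study.annotations, kind)
    dend = hcluster_rows(sm.values)              # Euclidean, complete linkage
    fit = fit_glm_log_link(dend.heights)
    assign = choose_cluster_count(dend, fit)
    print(f"{kind} matrix ({sm.values.shape[0]} terms x {sm.values.shape[1]} comparisons)")
    print(sm.values.round(3).to_string())
    print(f"  GLM fit: h_i ~ exp({fit.beta0:.3f} + {fit.beta1:.3f} * i); "
          f"first above-trend merge i* = {assign.i_star} -> k = {assign.k} clusters")
    for c in range(1, assign.k + 1):
        members = sorted(t for t, ci in assign.assignment.items() if ci == c)
        print(f"  cluster {c}: {', '.join(members)}")
    print()

# The ratio score is the fraction of each term's genes that are DEG
# interactors; the fc_weighted score multiplies it by the summed |log2FC|
# of those genes, so comparisons with stronger expression shifts dominate.
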