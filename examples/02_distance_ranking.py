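"""Rank two ground models against a spaceflight reference by S distance.

Intersects three per-study fold-change profiles onto their shared genes,
computes the pairwise L1 distance S = sum of |delta log2FC|, and ranks the
ground models by ascending S to the reference: a smaller S means the
model's transcriptome shift tracks the reference more closely.
"""

import numpy as np

import transcord as tc

rng = np.random.default_rng(7)
genes = [f"gene{i:03d}" for i in range(200)]
ref_fc = rng.normal(0, 1, size=200)

def noisy(fc, rho):
    return rho * fc + np.sqrt(1 - rho**2) * rng.normal(0, 1, size=len(fc))

profiles = [
    tc.StudyProfile.from_effects("FL", [(g, f, 0.5) for g, f in zip(genes, ref_fc)]),
    tc.StudyProfile.from_effects("CS", [(g, f, 0.5) for g, f in zip(genes, noisy(ref_fc, 0.8))]),
    tc.StudyProfile.from_effects("HU", [(g, f, 0.5) for g, f in zip(genes, noisy(ref_fc, 0.2))]),
]

matrix = tc.intersect_profiles(profiles)
dm = tc.distance_matrix(matrix)
print(f"shared genes: {dm.n_genes}")
for a, b in [("CS", "FL"), ("HU", "FL"), ("CS", "HU")]:
    print(f"S_{a}/{b} = {dm.s(a, b):8.2f}   (per gene {dm.s(a, b) / dm.n_genes:.3f})")

print("\nranking vs FL (ascending S = most similar first):")
for label, s in tc.rank_by_similarity(dm, "FL"):
    print(f"  {label}: S = {s:.2f}")

print("\ntop 3 genes driving S_CS/FL:")
for gene, delta in tc.gene_contributions(matrix, "CS", "FL", top_k=3):
    print(f"  {gene}: |delta log2FC| = {delta:.3f}")
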