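"""Generate a synthetic multi-disease GWAS bundle with planted genes.

Writes every input the pipeline consumes (summary statistics, LD blocks,
LD scores, gene annotation, variant consequences, evidence scores, gene
sets, disease metadata) and prints the planted ground truth.
"""

from pleioscan.simulate import default_config, write_fixture_bundle

cfg = default_config(seed=0)
out = write_fixture_bundle(cfg, "scratch/bundle")
print(f"bundle written to {out}")
print(f"{cfg.n_diseases} diseases, {cfg.n_snps} SNPs in {cfg.n_blocks} "
      f"LD blocks, {cfg.n_genes} genes")
print("planted causal genes (gene -> diseases, per-SNP noncentrality):")
for pg in cfg.planted_genes:
    print(f"  {pg.gene_id} -> {','.join(pg.diseases)}  lam={pg.lam}")
# Each planted gene seeds genuine association signals in its disease
# subset; everything else is polygenic background plus noise.
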