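"""Pooled wild-type scan and T1 -> T2 heritability checks.

Stunted seedlings are often genotyped as one bulk DNA pool: if no wild-type
reads appear at any gene, the pool is consistent with every plant being a
homozygous/biallelic mutant. Selfing a T1 plant should transmit the same
indel alleles to T-DNA-free T2 plants; `compare_generations` verifies that.
"""

from cas12mux import SimulationConfig, simulate_population
from cas12mux.calling import infer_pool_homozygosity, pooled_wt_fraction
from cas12mux.model import Zygosity
from cas12mux.pipeline import genotype_population
from cas12mux.zygosity import compare_generations

# --- pooled scan over an all-mutant "Type-2" batch
cfg = SimulationConfig(n_plants=20, seed=23,
                       class_probs={"Ho": 0.6, "Bi": 0.4})
pop = simulate_population(cfg)
for site in list(cfg.genes)[:3]:
    pools = [pop.reads[(pid, site.gene_id)] for pid in pop.plant_ids]
    wt = pooled_wt_fraction(pools, site)
    print(f"{site.gene_id}: pooled WT read fraction {wt:.4f} "
          f"-> {infer_pool_homozygosity(wt)}")

# --- heritability: a T2 plant fixes one allele of each biallelic T1 gene
plants = genotype_population(list(cfg.genes), pop.reads)
t1 = plants[0]
t2_calls = {}
for gene, call in t1.gene_calls.items():
    if call.zygosity_class is Zygosity.BI:
        kept = call.allele_calls[0]  # selfing fixed the first allele
        from cas12mux.model import AlleleCall, GeneZygosity
        t2_calls[gene] = GeneZygosity(
            gene, Zygosity.HO, (AlleleCall(kept.allele, 100, 1.0),), 0.0)
    else:
        t2_calls[gene] = call
from cas12mux.model import PlantGenotype
t2 = PlantGenotype(f"{t1.plant_id}-T2-1", t2_calls,
                   t1.is_sextuple_no_wt, t1.is_full_lof, t1.predicted_type3)
verdict = compare_generations(t1, t2)
print(f"\n{t1.plant_id} -> {t2.plant_id}: overall heritable = {verdict.overall}")
for gene, v in verdict.per_gene.items():
    print(f"  {gene}: {v}")

# "heritable" means the T2 mutant allele set is a nonempty subset of the
# T1 alleles (Mendelian fixation); a novel allele or a WT reversion at a
# Ho/Bi gene would be flagged instead.
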