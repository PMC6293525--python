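# ccqg pipeline configuration template.
# Every key is optional; omitted keys fall back to the defaults shown here.
# Run with:  ccqg run --config examples/config.yaml --outdir demo_run

seed: 1                      # master seed; each stage derives its own child seed
outdir: ccqg_run             # output directory (overridable with --outdir)
trait: trait                 # name of the simulated / analysed trait column

simulate:
  n_lines: 20                # CC lines to breed
  chr_lengths_cM: [70.0, 70.0]   # one entry per autosome
  markers_per_chrom: 250     # SNPs per chromosome, uniform in cM
  allele_freq: 0.5           # founder alternate-allele frequency
  inbreeding_gens: 20        # sib-mating generations after the funnel (F20-like)
  funnels: balanced          # balanced | null (random permutation per line)
  genotype_error_rate: 0.005 # per-call symmetric genotyping error
  genotype_missing_rate: 0.02
  n_per_line: [5, 6]         # animals per line (int, or [lo, hi] inclusive)
  sigma_g2: 0.0              # polygenic variance (kinship-structured)
  sigma_e2: 1.0              # residual variance per animal
  age_effect: 0.0            # phenotype units per day of age
  qtls: []                   # planted QTLs, e.g.:
  # - chrom: "1"
  #   pos_cm: 30.0
  #   effects: [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]   # one per founder

hmm:
  error_rate: 0.01           # emission epsilon (also absorbs heterozygosity)
  expansion: 2.0             # map-expansion factor a in r = (1-exp(-a d/50))/2
  prune_to: null             # thin intervals to ~N (null = keep all)

preprocessing:
  covariates: [age, batch, origin]
  quantile_normalize: true   # Blom inverse-normal transform after correction

scan:
  n_perm: 200                # permutations for genome-wide thresholds (>=100)
  alphas: [0.05, 0.1, 0.5]   # threshold levels to report
  alpha: 0.05                # significance level for the QTL table

annotate:
  enabled: false             # overlap QTLs with a gene table + ranking
  n_genes: 500               # simulated gene table size if no paths given
  n_resample: 2000
  # gene_table: genes.tsv    # BED-like TSV (chrom, start, end, gene_id, ...)
  # ranking: ranking.csv     # two-column CSV: gene_id, rank (1 = most implicated)
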