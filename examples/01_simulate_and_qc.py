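"""Simulate a multi-parent RIL population and run genotype quality control.

Prints the SNP counts before and after the het-to-missing + MAF/missing-rate
filters; removed SNPs are monomorphic in the sample or too often missing.
"""

from hapsparse import SimConfig, het_to_missing, qc_filter, simulate_genotypes

cfg = SimConfig(n_lines=150, n_chrom=3, snps_per_chrom=60, missing_rate=0.03, seed=4)
g, truth = simulate_genotypes(cfg)
print(f"simulated {g.n_lines} inbred lines x {g.n_snps} SNPs "
      f"({len(truth.blocks)} ancestry blocks)")

g = het_to_missing(g)
g, report = qc_filter(g, maf_min=0.05, miss_max=0.1)
print(f"QC: {report.n_snps_in} SNPs in, {report.n_removed_maf} removed for "
      f"MAF < 0.05, {report.n_removed_missing} for missing rate > 0.1, "
      f"{report.n_snps_out} retained")
# The retained SNPs are what every downstream stage (blocks, kinship) uses.
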