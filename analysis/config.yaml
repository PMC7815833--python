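# Study conditions for the analysis run: a two-species genome carried
# through three rounds of whole-genome duplication, 50 miRNA families,
# five tissues per species, and a 10% planted species arm-switch rate.
simulation:
  n_chromosomes: 2
  genes_per_chromosome: 120
  n_mirna_families: 50
  rounds: 3
  retention_prob: 0.7
  species_split: true
  switch_fraction: 0.1
  n_samples_per_species: 5
  reads_per_locus_mean: 100
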