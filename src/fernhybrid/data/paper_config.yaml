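# Default study-design configuration for the synthetic generator.
#
# Two mangrove fern species (species_A = Acrostichum aureum, species_B =
# A. speciosum) with low within-species diversity, sampled across the
# populations and sample sizes of the field study; 22 putative hybrids, all
# F1, all with a species-B (maternal) chloroplast. Locus lengths and
# fixed-difference counts are the published aligned lengths and divergence
# counts; within-species haplotype counts match the published panels
# (2&2 / 6&2 / 6&3). Per-population haplotype frequencies are plausible
# values (the source reports them only graphically): the dominant haplotype
# carries most of the mass, one A-population is the only one with the cam
# variant, one is gapCp1-monomorphic, and the rarer gapCp1 species-B
# haplotype is private to one location.
schema_version: 1
loci:
  - name: cam
    letter: A
    length: 453
    fixed_substitutions: 9
    indels: []
    haplotypes:
      species_A: [0, 1]          # extra mutations off the species core
      species_B: [0, 1]
    frequencies:
      species_A:
        default: [1.0, 0.0]
        Danzhou: [0.7, 0.3]
      species_B:
        default: [0.6, 0.4]
        Suixi: [0.8, 0.2]
  - name: gapCp1
    letter: B
    length: 601
    fixed_substitutions: 11
    indels:
      - {length: 5, at: 0.72}    # the fixed 5-bp interspecific indel
    haplotypes:
      species_A: [0, 1, 1, 1, 2, 2]
      species_B: [0, 1]
    frequencies:
      species_A:
        default: [0.6, 0.1, 0.1, 0.08, 0.07, 0.05]
        Huizhou: [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
      species_B:
        default: [1.0, 0.0]
        Wenchang: [0.8, 0.2]     # sB2 private to Wenchang
  - name: gapCp2
    letter: C
    length: 490
    fixed_substitutions: 7
    indels: []
    haplotypes:
      species_A: [0, 1, 1, 1, 2, 2]
      species_B: [0, 1, 1]
    frequencies:
      species_A:
        default: [0.55, 0.12, 0.1, 0.09, 0.08, 0.06]
      species_B:
        default: [0.5, 0.3, 0.2]
chloroplast:
  name: trnV-trnM
  letter: T
  length: 975
  fixed_substitutions: 11
  indels:
    - {length: 4, at: 0.2}
    - {length: 6, at: 0.5}
    - {length: 3, at: 0.8}
populations:
  species_A:
    Wenchang: 21
    Sanya: 21
    Qionghai: 15
    Haikou: 21
    Danzhou: 23
    Huizhou: 22
    Guangzhou: 21
    Suixi: 13
  species_B:
    Gaoqiao: 21
    Wenchang: 25
    Suixi: 24
hybrids:
  populations:
    Wenchang: 10
    Suixi: 12
  classes:
    F1: 22
    F2: 0
    BC_A: 0
    BC_B: 0
maternal_rule: always_B
sequencing_error_rate: 0.0
germination:
  species_A: {rate: 0.798, spores: 240}
  species_B: {rate: 0.654, spores: 230}
  hybrid: {rate: 0.203, spores: 250}
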