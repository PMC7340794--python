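# Radial labeling geometries for the microtubule forward model.
#
# All lengths are nm.  label_inner / label_outer bound the fluorophore shell
# as radial offsets beyond the 12.5 nm microtubule surface; ring_weight is
# the fraction of dye concentrated in a thin ring at the outer shell edge
# (the rest is uniform over the shell); sigma_loc is the image-scale
# localization-precision blur.  The numerical values are pinned so that the
# predicted peak-to-peak distances reproduce the published simulations for
# each labeling protocol; see docs/methods.md for the calibration rationale.
#
# Offsets in brief:
#   * pre-expansion IgG stack: dye layer at 11.9 nm (digestion-compacted
#     primary+secondary stack, 93% of dye in the terminal layer)
#   * post-expansion IgG stack: intact, fully extended at the 17.5 nm
#     linkage error; does not expand with the gel
#   * 42-base DNA linkers: dye sits 4 bases in from the strand end
#     (38 x 0.34 nm = 12.92 nm effective contour), attached at the
#     antibody conjugation site; extended (dsDNA, gel-anchored radial),
#     coiled (ssDNA worm-like chain, persistence length 5 nm) or
#     orientationally relaxed (unexpanded, hemisphere-averaged)
geometries:
  igg_pre:
    description: primary + secondary IgG, labeled before expansion
    structure_radius: 12.5
    label_inner: 0.0
    label_outer: 11.9
    ring_weight: 0.93
    ring_thickness: 1.0
    expands_structure: true
    expands_linker: true
    sigma_loc: 3.0
  igg_post:
    description: primary + secondary IgG, applied after expansion (intact stack)
    structure_radius: 12.5
    label_inner: 0.0
    label_outer: 17.5
    ring_weight: 0.93
    ring_thickness: 1.0
    expands_structure: true
    expands_linker: false
    sigma_loc: 3.0
  dna42_dsdna:
    description: 42-base trifunctional oligo, hybridized pre-gelation, gel-extended
    structure_radius: 12.5
    label_inner: 0.0
    label_outer: 24.82   # 11.9 + 38 x 0.34
    ring_weight: 1.0
    ring_thickness: 1.0
    expands_structure: true
    expands_linker: true
    sigma_loc: 3.0
    linker_conformation: extended
    dna_bases: 42
  dna42_ssdna:
    description: 42-base single-stranded anchor, coiled during gelation
    structure_radius: 12.5
    label_inner: 0.0
    label_outer: 21.01   # 11.9 + WLC rms end-to-end of the 12.92 nm contour
    ring_weight: 1.0
    ring_thickness: 1.0
    expands_structure: true
    expands_linker: true
    sigma_loc: 3.0
    linker_conformation: coiled
    dna_bases: 42
  dna42_relaxed:
    description: 42-base DNA antibody, unexpanded (orientationally disordered linker)
    structure_radius: 12.5
    label_inner: 11.1
    label_outer: 24.02   # 11.1 + 38 x 0.34, hemisphere-averaged radial offsets
    ring_weight: 0.0
    ring_thickness: 1.0
    expands_structure: true
    expands_linker: true
    sigma_loc: 3.0
    linker_conformation: relaxed
    dna_bases: 42
mixtures:
  pre_post_mix:
    description: pre- plus post-expansion labeling, pre signal diluted ~1/e^2
    pre: igg_pre
    post: igg_post
    ratio: 0.1
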