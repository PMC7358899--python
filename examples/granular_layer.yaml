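# Cerebellar granular layer, desk scale (350 x 350 x 100 um).
# Populations are generated in list order by maximal Poisson-disk packing in
# a box extended by 25 um per side; 25 um boundary strips are trimmed.
domain:
  extents: [350, 350, 100]
  extension_margin: 25
  trim_margin: 25

populations:
  - {name: goc, density: 9500, min_distance: 45, softness: 1, diameter: 27}
  # glomeruli: sampled with the sagittal axis squeezed to 1/3, so their
  # real-space sagittal spacing is three times the mediolateral one
  - {name: glo, density: 570000, min_distance: 8.39, softness: 1,
     anisotropy_scale: [1, 0.33333333333333, 1]}
  - {name: gc, density: 1900000, min_distance: 6.15, softness: 0.2}

morphology:
  # two apical (25 pts) and two basal (12 pts) dendrites per Golgi cell;
  # lengths are placeholder model inputs
  - {population: goc, kind: goc_dendrites,
     params: {apical_length: 150, basal_length: 80}}
  # granule-cell axons: vertical ascending axon branching 50-150 um above
  # the soma, parallel fiber extending +-500 um mediolaterally
  - {population: gc, kind: gc_axon,
     params: {aa_height: [50, 150], pf_half_length: 500}}

connections:
  # anisotropic somatic search: mediolateral radius 7.85 um, sagittal
  # coordinates squeezed by 1/4 (real sagittal reach 4 x 7.85 um)
  - {name: gc_glo, kind: point, source: gc, target: glo,
     radius: 7.85, metric_scale: [1, 0.25, 1]}
  # axon-dendrite contacts by the 2D projection method
  - {name: aa_goc, kind: projection, source: "gc:aa", target: "goc:dendrites",
     radius: 3.0}
  - {name: pf_goc, kind: projection, source: "gc:pf", target: "goc:dendrites",
     radius: 3.0}

segment_length: 10
seed: 0
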