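# Versioned region/mask definitions for the circular 16,569-bp rCRS.
# Site counts follow the "paper_table2" preset (the integers the published
# per-region rates were computed with); see mitorate.genome.SITE_COUNT_PRESETS
# for the strict-rCRS alternative.
version: 1
regions:
  mtGenome:
    intervals: [[1, 16569]]
    site_count: 16596
  HVI:
    intervals: [[16024, 16383]]
    site_count: 359
  HVII:
    intervals: [[57, 371]]
    site_count: 314
  HVI_HVII:
    intervals: [[16024, 16383], [57, 371]]
    site_count: 673
  control:
    intervals: [[16024, 576]]   # wraps past the origin
    site_count: 1149
  coding:
    intervals: [[577, 16023]]
    site_count: 15447
mask:
  positions: [309, 455, 463, 573, 960, 5899, 8276, 8285, 16193]
  ranges: [[16180, 16183], [302, 316], [16183, 16194]]
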