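# Versioned condition presets for the default synthetic study.
#
# All entries are multiplicative factors on the base GeneratorParams.
#
# surrogate_base: formulation differences shared by every skin section of a
#   stratum.  The hydrophilic surrogate (aqueous) deposits a deeply
#   penetrating signal; the lipophilic surrogate (in oil) deposits a larger
#   surface amount with a much shorter depth scale.
#
# modifiers encode the treatment effects qualitatively:
#   * professional treatment (sections 2 and 3) cleanses the skin, removing
#     strongly autofluorescent sebum/bacteria hotspots (hotspot_density 0)
#     and hydrating the SC during the treatment (hydration_index up);
#   * AI applied DURING the treatment is partly lost to the towel mask and,
#     with massage, additionally rubbed away: dye_amount fractions 0.80/0.54
#     (hydrophilic, sections 2/3) and 0.66/0.32 (lipophilic), with a reduced
#     depth scale for the lipophilic AI;
#   * AI applied AFTER the treatment benefits from the hydrated, massaged SC:
#     massage (section 3) raises amount and depth scale (strongly so for the
#     lipophilic AI, whose blocking water front it removes), whereas the
#     non-massaged skin (section 2) has dried out and blocks the lipophilic
#     AI (amount and depth scale down) while mildly helping the hydrophilic.
version: 1
surrogate_base:
  hydrophilic: {}                       # base params are the hydrophilic formulation
  lipophilic: {dye_amount: 1.6, dye_decay_um: 0.3636}
conditions:
  - {skin_section: 1, surrogate: hydrophilic, timepoint: during, modifiers: {}}
  - {skin_section: 1, surrogate: hydrophilic, timepoint: after,  modifiers: {}}
  - {skin_section: 1, surrogate: lipophilic,  timepoint: during, modifiers: {}}
  - {skin_section: 1, surrogate: lipophilic,  timepoint: after,  modifiers: {}}
  - {skin_section: 2, surrogate: hydrophilic, timepoint: during,
     modifiers: {dye_amount: 0.80, hotspot_density: 0.0, hydration_index: 1.6}}
  - {skin_section: 3, surrogate: hydrophilic, timepoint: during,
     modifiers: {dye_amount: 0.54, hotspot_density: 0.0, hydration_index: 1.6}}
  - {skin_section: 2, surrogate: hydrophilic, timepoint: after,
     modifiers: {dye_amount: 1.15, hotspot_density: 0.0, hydration_index: 0.8}}
  - {skin_section: 3, surrogate: hydrophilic, timepoint: after,
     modifiers: {dye_amount: 1.25, hotspot_density: 0.0, hydration_index: 1.3}}
  - {skin_section: 2, surrogate: lipophilic, timepoint: during,
     modifiers: {dye_amount: 0.66, dye_decay_um: 0.45, hotspot_density: 0.0, hydration_index: 1.6}}
  - {skin_section: 3, surrogate: lipophilic, timepoint: during,
     modifiers: {dye_amount: 0.32, dye_decay_um: 0.45, hotspot_density: 0.0, hydration_index: 1.6}}
  - {skin_section: 2, surrogate: lipophilic, timepoint: after,
     modifiers: {dye_amount: 0.70, dye_decay_um: 0.40, hotspot_density: 0.0, hydration_index: 0.8}}
  - {skin_section: 3, surrogate: lipophilic, timepoint: after,
     modifiers: {dye_amount: 1.50, dye_decay_um: 1.20, hotspot_density: 0.0, hydration_index: 1.3}}
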