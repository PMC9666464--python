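# Closed vocabulary of benthic functional-group codes.
#
# Flags:
#   calcifier      - contributes to gross carbonate production (via the trait
#                    table, which must carry a row for the code).
#   dead_substrate - counts toward the dead-coral-substrate cover that drives
#                    microbioerosion. Turf is excluded by default; flip the
#                    flag here to include it.
#   clionid        - counts toward the clionid-sponge cover that drives
#                    macrobioerosion. Other sponges deliberately do not.
groups:
  CCA:            {calcifier: true,  dead_substrate: false, clionid: false}
  hydrocoral:     {calcifier: true,  dead_substrate: false, clionid: false}
  macroalgae:     {calcifier: false, dead_substrate: false, clionid: false}
  turf:           {calcifier: false, dead_substrate: false, clionid: false}
  soft_coral:     {calcifier: false, dead_substrate: false, clionid: false}
  sponge:         {calcifier: false, dead_substrate: false, clionid: false}
  clionid_sponge: {calcifier: false, dead_substrate: false, clionid: true}
  seagrass:       {calcifier: false, dead_substrate: false, clionid: false}
  bare:           {calcifier: false, dead_substrate: true,  clionid: false}
  sand:           {calcifier: false, dead_substrate: false, clionid: false}
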