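# Variant of the default mouse network with direct edges between the three
# adipose depots, for sensitivity analysis of the B/N2 split when adipose
# tissues are treated as exchanging lipids directly rather than only via
# the circulation.
name: mouse_adipose_linked
compartments:
  - plasma
  - liver
  - heart
  - lung
  - kidney
  - small intestine
  - gastrocnemius
  - BAT
  - iWAT
  - eWAT
edges:
  - [plasma, liver]
  - [plasma, heart]
  - [plasma, lung]
  - [plasma, kidney]
  - [plasma, small intestine]
  - [plasma, gastrocnemius]
  - [plasma, BAT]
  - [plasma, iWAT]
  - [plasma, eWAT]
  - [small intestine, liver]
  - [BAT, iWAT]
  - [BAT, eWAT]
  - [iWAT, eWAT]
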