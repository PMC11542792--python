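# Default mouse compartment network: the circulation (plasma) exchanges
# lipids with every peripheral tissue, and the small intestine feeds the
# liver through the portal circulation.  Edit or replace this file to use
# a different adjacency structure.
name: mouse_default
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
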