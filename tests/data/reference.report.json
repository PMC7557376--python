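{
  "confirmation_by_community": [
    {
      "community": 1,
      "database_pct": 50.0,
      "literature_pct": 35.0,
      "not_confirmed_pct": 15.0,
      "size": 20
    },
    {
      "community": 2,
      "database_pct": 45.0,
      "literature_pct": 35.0,
      "not_confirmed_pct": 20.0,
      "size": 20
    },
    {
      "community": 3,
      "database_pct": 70.0,
      "literature_pct": 15.0,
      "not_confirmed_pct": 15.0,
      "size": 20
    }
  ],
  "hints": [
    "D0022",
    "D0059"
  ],
  "layout_partition_nmi": 1.0,
  "method": "recursive_bisection",
  "modularity": 0.3894280107865674,
  "n_communities": 3,
  "n_drugs_input": 60,
  "n_edges": 1171,
  "n_hints": 2,
  "n_nodes": 60,
  "overall_confirmation_rate_pct": 83.33333333333333,
  "powerlaw": {
    "bd": {
      "alpha": 4.573721877017616,
      "ks": 0.13669170779238315,
      "n_tail": 30,
      "xmin": 0.00014386704653215955
    },
    "betweenness": {
      "alpha": 3.1740511384257237,
      "ks": 0.12318422384479966,
      "n_tail": 31,
      "xmin": 0.0053204998136212826
    },
    "degree": {
      "alpha": 9.27515051603354,
      "ks": 0.13107548365700794,
      "n_tail": 24,
      "xmin": 42.0
    },
    "weighted_degree": {
      "alpha": 11.999995177972313,
      "ks": 0.13333784449890773,
      "n_tail": 14,
      "xmin": 116.0
    }
  },
  "seed": 42,
  "t": 5
}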