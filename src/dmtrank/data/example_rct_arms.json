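[
  {
    "trial": "EXAMPLE-NAT-RELAPSE",
    "dmt_id": "natalizumab",
    "outcome": "relapse",
    "duration_months": 24,
    "published_event_free": 0.67,
    "filters": {
      "age": [18, 50],
      "edss": [0, 5.0],
      "relapses_last_12m": [1, 99]
    }
  },
  {
    "trial": "EXAMPLE-NAT-CDP",
    "dmt_id": "natalizumab",
    "outcome": "cdp",
    "duration_months": 24,
    "published_event_free": 0.83,
    "filters": {
      "age": [18, 50],
      "edss": [0, 5.0],
      "relapses_last_12m": [1, 99]
    }
  },
  {
    "trial": "EXAMPLE-FIN-RELAPSE",
    "dmt_id": "fingolimod",
    "outcome": "relapse",
    "duration_months": 24,
    "published_event_free": 0.70,
    "filters": {
      "age": [18, 55],
      "edss": [0, 5.5],
      "relapses_last_12m": [1, 99],
      "time_since_diagnosis": [0, 240]
    }
  },
  {
    "trial": "EXAMPLE-DMF-RELAPSE",
    "dmt_id": "dimethyl_fumarate",
    "outcome": "relapse",
    "duration_months": 24,
    "published_event_free": 0.55,
    "filters": {
      "age": [18, 55],
      "edss": [0, 5.0]
    }
  },
  {
    "trial": "EXAMPLE-TER-RELAPSE",
    "dmt_id": "teriflunomide",
    "outcome": "relapse",
    "duration_months": 24,
    "published_event_free": 0.52,
    "filters": {
      "age": [18, 55],
      "edss": [0, 5.5]
    }
  },
  {
    "trial": "EXAMPLE-IFN-CDP",
    "dmt_id": "interferon_beta",
    "outcome": "cdp",
    "duration_months": 24,
    "published_event_free": 0.78,
    "filters": {
      "age": [18, 50],
      "edss": [0, 5.5],
      "relapses_last_12m": [1, 99]
    }
  }
]
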