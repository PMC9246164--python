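{
  "nodes": [
    {
      "id": -1,
      "role": "input",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.0,
      "response": 1.0
    },
    {
      "id": -2,
      "role": "input",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.0,
      "response": 1.0
    },
    {
      "id": -3,
      "role": "input",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.0,
      "response": 1.0
    },
    {
      "id": -4,
      "role": "input",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.0,
      "response": 1.0
    },
    {
      "id": 0,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -0.9,
      "response": 1.0
    },
    {
      "id": 1,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -5.0,
      "response": 1.0
    },
    {
      "id": 2,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.235,
      "response": 1.0
    },
    {
      "id": 3,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -5.0,
      "response": 1.0
    },
    {
      "id": 4,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 0.55,
      "response": 1.0
    },
    {
      "id": 5,
      "role": "output",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -5.0,
      "response": 1.0
    },
    {
      "id": 6,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": 34.5,
      "response": 150.0
    },
    {
      "id": 7,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -8.0,
      "response": 1.0
    },
    {
      "id": 8,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -10.0,
      "response": 20.0
    },
    {
      "id": 9,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -10.0,
      "response": 20.0
    },
    {
      "id": 10,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -24.0,
      "response": 60.0
    },
    {
      "id": 11,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -21.5,
      "response": 50.0
    },
    {
      "id": 12,
      "role": "hidden",
      "activation": "sigmoid",
      "aggregation": "sum",
      "bias": -87.0,
      "response": 150.0
    }
  ],
  "connections": [
    {
      "source": -1,
      "target": 4,
      "weight": 0.35,
      "enabled": true
    },
    {
      "source": -4,
      "target": 0,
      "weight": 3.6,
      "enabled": true
    },
    {
      "source": 0,
      "target": 0,
      "weight": -3.5,
      "enabled": true
    },
    {
      "source": -2,
      "target": 2,
      "weight": 0.56,
      "enabled": true
    },
    {
      "source": 0,
      "target": 6,
      "weight": -1.0,
      "enabled": true
    },
    {
      "source": 6,
      "target": 8,
      "weight": 1.0,
      "enabled": true
    },
    {
      "source": 8,
      "target": 9,
      "weight": 1.0,
      "enabled": true
    },
    {
      "source": 9,
      "target": 7,
      "weight": 16.0,
      "enabled": true
    },
    {
      "source": 7,
      "target": 2,
      "weight": -6.0,
      "enabled": true
    },
    {
      "source": 0,
      "target": 10,
      "weight": 1.0,
      "enabled": true
    },
    {
      "source": 10,
      "target": 2,
      "weight": -6.0,
      "enabled": true
    },
    {
      "source": 0,
      "target": 11,
      "weight": 1.0,
      "enabled": true
    },
    {
      "source": 11,
      "target": 2,
      "weight": -6.0,
      "enabled": true
    },
    {
      "source": 0,
      "target": 12,
      "weight": 1.0,
      "enabled": true
    },
    {
      "source": 12,
      "target": 2,
      "weight": 14.0,
      "enabled": true
    },
    {
      "source": -3,
      "target": 3,
      "weight": 1.0,
      "enabled": false
    }
  ],
  "metadata": {
    "name": "paradoxical-lesion motif",
    "weights": {
      "(-1 -> 4)": 0.35,
      "(-4 -> 0)": 3.6,
      "(0 -> 0)": -3.5,
      "(-2 -> 2)": 0.56,
      "(0 -> 6)": -1.0,
      "(6 -> 8)": 1.0,
      "(8 -> 9)": 1.0,
      "(9 -> 7)": 16.0,
      "(7 -> 2)": -6.0,
      "(0 -> 10)": 1.0,
      "(10 -> 2)": -6.0,
      "(0 -> 11)": 1.0,
      "(11 -> 2)": -6.0,
      "(0 -> 12)": 1.0,
      "(12 -> 2)": 14.0
    },
    "biases": {
      "node0": -0.9,
      "node2": 0.235,
      "node4": 0.55,
      "inert": -5.0,
      "band": 34.5,
      "relay": -10.0,
      "gate": -8.0,
      "hi1": -24.0,
      "hi2": -21.5,
      "runaway": -87.0
    },
    "responses": {
      "band": 150.0,
      "relay": 20.0,
      "hi1": 60.0,
      "hi2": 50.0,
      "runaway": 150.0
    },
    "sigmoid": "plain logistic 1/(1+exp(-z)), z clamped to [-60, 60]"
  }
}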