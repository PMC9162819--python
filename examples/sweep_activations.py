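"""Sweep the network's hidden activation over the supported family.

Reproduces the activation-selection experiment design: train the same
architecture with each activation (3 seeds each) and compare mean held-out
accuracy on a synthetic table with a clear planted signal.
"""

from hho_featsel import ExperimentSpec, SyntheticSpec, sweep
from hho_featsel.classifiers import DnnSpec

spec = ExperimentSpec(data=SyntheticSpec(n_rows=400, effect_size=2.0, seed=1))
spec.dnn = DnnSpec(hidden_layers=(16, 8), epochs=100)

frame = sweep(
    "activation",
    ["relu", "elu", "tanh", "softmax", "selu", "softplus", "softsign"],
    spec,
    n_seeds=3,
)
print(frame.round(3).to_string(index=False))
# Each row is one activation; accuracies are means over three seeded runs.
# On easy data every activation clears ~0.9; differences grow on harder
# tables and with tighter epoch budgets.
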