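"""The three benchmark degree laws: pmf values, means, and tail behaviour.

Prints the model mean degree and the probabilities f(1)..f(5) for the
zero-truncated Poisson(2) law and the two polylogarithmic laws.  The mean of
polylog(0.1, 2) is the 2.42 reference value used throughout the synthetic
studies; polylog(2, 3) is the sparsest law, whose tiny f(4) and f(5) are what
break the SRS competitor intervals.
"""

import patchboot as pb

models = {
    "ztp(2)": pb.ztp(2),
    "polylog(0.1, 2)": pb.polylog_model(0.1, 2),
    "polylog(2, 3)": pb.polylog_model(2, 3),
}

for name, model in models.items():
    fk = ", ".join(f"f({k})={model.pmf(k):.4f}" for k in range(1, 6))
    print(f"{name:16s} mean={model.mean():.4f}  {fk}")
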