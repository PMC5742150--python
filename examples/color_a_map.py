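"""Three-color the Canadian provinces/territories map with a spiking network.

Compiles the 13-vertex adjacency graph into a winner-take-all network
(one sub-population per region × color), drives it with Poisson noise, and
decodes the first stable satisfying coloring.
"""

from spikesat import load_fixture, run_single

inst = load_fixture("canada")
result = run_single(inst, seed=1, duration_ms=30_000, stop="stable")

regions = inst.metadata["vertices"]
colors = "red green blue".split()
print(f"first satisfaction at {result.t_first_ms / 1000:.2f} s of model time")
print(f"stable satisfaction from {result.t_stable_ms / 1000:.2f} s")
for region, value in zip(regions, result.assignment.values):
    print(f"  {region:3s} -> {colors[value]}")
# The solve times are model (biological) time: the network ran that many
# milliseconds of 1 ms steps before every adjacency constraint held at once.
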