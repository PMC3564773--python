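"""Rank model parameters by local sensitivity of the fitted model.

Computes normalised central-difference sensitivities of ROS and aperture
(at 15-60 min, under the three experimental treatments) to each of the 28
free parameters, and prints the ranking.  On this output window the
turnover parameters of the NO and basal-antioxidant balances (beta30,
beta11, alpha31, ...) carry the largest raw-output elasticities; the
antioxidant cascade rates (alpha23, beta13) sit mid-field because their
delayed action modulates only part of the ROS removal within 60 min (see
docs/methods.md for the structural analysis).
"""

import guardcell as gc

params = gc.load_reference_params()
report = gc.local_sensitivity(params)
print(report.output_spec)
print(f"\n{'rank':>4} {'parameter':>10} {'|index|':>9}")
for rank, name in enumerate(report.ranking[:10], start=1):
    print(f"{rank:>4} {name:>10} {abs(report.indices[name]):>9.3f}")
print("\ntop two:", gc.rank_parameters(report, 2))
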