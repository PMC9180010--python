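"""Audit the default architecture: layer trace, parameters, FLOPs,
receptive field, and the depth-ablation ordering.

Run:  python examples/profile_architecture.py
"""

from mvdnet import MVDNetSpec, count_flops, count_parameters, profile

report = profile(MVDNetSpec())
print(report.to_tsv())
print(f"trainable parameters : {report.params_exact:,}  "
      f"({report.params_millions} M)")
print(f"FLOPs @512x512       : {report.flops_g:.2f} G   ({report.flop_convention})")
print(f"encoder receptive field: {report.receptive_field} px")

# Deeper encoders cost more; the audit reproduces the depth ordering.
print("\ndepths (n,m,l)  params(M)  FLOPs(G)")
for depths in [(2, 2, 2), (2, 2, 4), (2, 4, 4), (4, 4, 4), (2, 8, 8)]:
    spec = MVDNetSpec(depths=depths)
    print(f"{depths!s:14}  {count_parameters(spec) / 1e6:8.3f}  "
          f"{count_flops(spec):8.2f}")
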