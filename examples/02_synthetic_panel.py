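"""Generate a study-scale synthetic crash panel and inspect its structure.

The default truth emulates the observed panel: 696 segments x 8 quarters,
covariates drawn with the published means/sds/proportions, counts from the
NB-Lindley hierarchy calibrated to the observed outcome moments.
"""

from nblcrash import TollCounts, compute_qadt, compute_vehicle_shares, default_truth, simulate_panel

panel = simulate_panel(default_truth(), 696, 8, seed=0)
print(f"panel: {panel.I} segments x {panel.T} quarters = {panel.n} cells")
print(f"mean crashes per cell: {panel.y.mean():.3f} (observed study value: 0.746)")
print(f"count variance:        {panel.y.var():.3f} (clearly overdispersed)")
print(f"zero fraction:         {panel.zero_fraction():.3f}")

# Exposure construction from raw toll counts: passenger-car-equivalent
# weights 1, 1.5, 2, 3, 3.5 for vehicle classes 1-5 over a 90-day quarter.
tc = TollCounts(v1=900, v2=60, v3=20, v4=15, v5=5, q=90)
shares = compute_vehicle_shares(tc)
print(f"\nQADT for a 900/60/20/15/5 toll quarter: {compute_qadt(tc):.3f} veh/day")
print("weighted class shares:", {c: round(s, 4) for c, s in shares.items()})
print("identity check  sum(weight*share) =",
      round(sum(w * shares[c] for c, w in zip(range(1, 6), (1, 1.5, 2, 3, 3.5))), 12))
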