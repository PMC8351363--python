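"""Descriptive statistics of a bipartite network.

Builds the Southern-Women events network size (18 women, 14 events, 89
attendance edges) from its counts and prints link density and average
degrees — the quick first look one takes at any bipartite dataset.
"""

from dhrls import network_stats_from_counts

stats = network_stats_from_counts(n_left=18, n_right=14, n_edges=89)

print(f"link density      LD  = {stats.link_density:.4f}")
print(f"average degree    AD  = {stats.avg_degree:.2f}")
print(f"left avg degree   LAD = {stats.left_avg_degree:.2f}")
print(f"right avg degree  RAD = {stats.right_avg_degree:.2f}")

# LD is the fraction of all possible woman-event pairs actually present
# (0.3532: a dense social network); LAD/RAD are edges per woman / per event.
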