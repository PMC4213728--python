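"""Segment a fictive swim motor pattern into bursts and episodes.

Simulates 2-min extracellular recordings for control-like and
Mn-treated-like larvae, detects spikes on the voltage trace with the
automatic robust threshold, sorts them by the 10 / 100 ms ISI rules
and prints the four motor-pattern metrics.  The treated pattern should
show more spikes per burst, longer bursts and a shorter cycle period.
"""

from numpy import mean

from larvamotor import detect_spikes, metrics, segment
from larvamotor.synthetic import simulate_spike_train, spike_train_preset

for preset in ("control", "mn"):
    sim = simulate_spike_train(spike_train_preset(preset, seed=4))
    spike_times = detect_spikes(sim.trace)  # auto threshold: median + 5 MAD/0.6745
    seg = segment(spike_times, intra_burst_isi_max=10.0, episode_isi_max=100.0)
    m = metrics(seg)
    print(f"[{preset}] {seg.n_spikes} spikes -> {seg.n_bursts} bursts in "
          f"{seg.n_episodes} episodes")
    print(f"  spikes/burst {mean(m.spikes_per_burst):.2f}, "
          f"burst duration {mean(m.burst_durations) * 1000:.1f} ms, "
          f"burst period {mean(m.burst_periods) * 1000:.1f} ms, "
          f"bursts/episode {mean(m.bursts_per_episode):.2f}")
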