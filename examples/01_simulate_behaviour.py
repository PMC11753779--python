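"""Simulate one stop-signal session and summarise the behaviour.

The staircase adapts the stop-signal delay (SSD) in 50 ms steps so that the
subject stops successfully on about half of the stop trials; failed-stop RTs
are faster than go RTs because the race censors slow go finishes.
"""

from sstpipe import RaceParams, get_design, simulate_session, summarize_behaviour

design = get_design("deHollander_7T")  # 384 trials, 25% stops, 4 staircases
params = RaceParams(go_mu=400, go_sigma=50, go_tau=60, stop_mu=200)

trials = simulate_session(design, params, seed=1)
s = summarize_behaviour(trials)

print(f"trials: {s.n_go} go + {s.n_stop} stop")
print(f"median go RT      : {s.median_go_rt_ms:6.1f} ms")
print(f"median failed-stop: {s.median_fs_rt_ms:6.1f} ms  (faster than go)")
print(f"stopping accuracy : {s.stop_accuracy_pct:6.1f} %   (staircase targets 50%)")
print(f"mean SSD          : {s.mean_ssd_ms:6.1f} ms")
print(f"SSRT (integration): {s.mean_ssrt_ms:6.1f} ms  (true stop latency 200 ms)")
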