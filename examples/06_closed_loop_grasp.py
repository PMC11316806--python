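"""Closed-loop reactive grasping: transduction controller vs constant MVC.

A 20 g weight is dropped on the grasped object at 500 ms.  The
transduction-function controller senses the impact through the tactile
stream and tightens the grip; a weak constant 10%-MVC grip drops the
object.  Prints the trial outcomes and a few log lines around impact.
"""

from tactosense import GraspPlant, GraspScenario, default_transduction_model, \
    run_closed_loop

plant = GraspPlant()
scenario = GraspScenario(mode="reactive", noise_sd=0.01, seed=0)

for name, controller in [("transduction", default_transduction_model("reactive")),
                         ("constant 10% MVC", 0.1),
                         ("constant 100% MVC", 1.0)]:
    log = run_closed_loop(controller, plant, scenario, seed=0)
    outcome = "LOST contact" if log["slip_flag"].any() else "held"
    print(f"{name:18s}: {outcome:12s} | final pressure "
          f"{log['pressure'].iloc[-1]:.3f} | peak grip {log['grip_cmd'].max():.3f}")

log = run_closed_loop(default_transduction_model("reactive"), plant, scenario,
                      seed=0)
window = log[(log.time_ms >= 450) & (log.time_ms <= 700) & (log.time_ms % 50 == 0)]
print("\ntransduction controller around the impact (t=500 ms):")
print(window[["time_ms", "pressure", "grip_cmd", "cuneate_rate"]]
      .round(3).to_string(index=False))

print("\nThe cuneate rate bursts at impact; the controller converts it into")
print("extra grip within ~150 ms (80 ms motor delay included), riding out")
print("the transient load that defeats the 10%-MVC constant grip.")
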