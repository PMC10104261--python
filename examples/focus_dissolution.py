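"""Focus lifespans through growth and division: condensate vs aggregate.

Generational dilution halves the protein concentration each division.
A condensate focus dissolves once the cell drops below its saturation
concentration; an insoluble aggregate persists indefinitely.  Foci are
tracked with LoG detection + gap-closing linking, and lifespans read off
the trajectory lengths (censored if the focus outlives the movie).
"""

from condenscan import dissolution as dz
from condenscan import simkit

CTX = dz.DissolutionContext(cells_divided_or_grew=True)

for mode in ("condensate", "aggregate"):
    mov = simkit.simulate_dissolution_series(
        mode, c_sat_uM=40.0, initial_concentration_uM=80.0,
        n_frames=40, rng=5,
        division_rule={"type": "deterministic", "molecule_fraction": 0.5})
    tracks, table, summary = dz.analyze_dissolution_movie(mov.stack,
                                                          context=CTX)
    per, course = dz.focus_intensity_course(tracks, mov.frame_interval)
    life = summary["mean_lifespan_h"]
    cen = summary["n_censored"]
    print(f"{mode}: measured lifespan {life:.2f} h "
          f"(truth {mov.lifespan_frames * mov.frame_interval / 3600:.2f} h), "
          f"censored tracks: {cen}")
    print(f"  focus intensity at mid-movie: "
          f"{course['mean'].iloc[min(10, len(course) - 1)]:.2f} of its "
          "starting value")
print("a ~10 h censored lifespan over a 10 h movie is the aggregate "
      "signature; dissolution within a few divisions marks a condensate")
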