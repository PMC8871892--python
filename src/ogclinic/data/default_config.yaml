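# Default clinic configuration: a dual-practice O&G outpatient clinic inside a
# public tertiary hospital.  Printed process-time quartiles (minutes) and daily
# volumes come from the source time-motion study; front-end counter service
# medians, the transfer time and the downtime rate are calibrated so that the
# simulated base case reproduces the observed turnaround-time medians.
# All clock fields are HH:MM (24-hour); all durations are minutes.

volumes:
  public_per_day: 86        # average public O&G patients on a working day
  private_per_day: 7        # average private O&G patients on a working day
  general_per_day: 867      # non-O&G patients sharing the QMS/revenue counters

attributes:
  # Obs : Gyn split among public patients (observed 180 : 177)
  p_obs: 0.5042016806722689
  needs_lab:
    PUBLIC_OBS: 0.2833333333333333   # 51 / 180
    PUBLIC_GYN: 0.0                  # Gyn lab cases were excluded upstream
    PRIVATE: 0.65625                 # 21 / 32
  p_specialist_discussion: 0.10      # public patients only
  p_elderly: 0.15                    # no effect on flow; kept as an attribute
  p_walk_in: 0.0

# (q1, median, q3) per station and patient class; "default" applies to any
# class without its own row.  QMS / REVENUE / OG_COUNTER medians are
# calibrated (shape fixed at 0.6/1.0/1.6 x median).
service_times:
  QMS:
    default: [0.2987, 0.4979, 0.7966]
  REVENUE:
    default: [0.45, 0.75, 1.2]
  OG_COUNTER:
    default: [0.9, 1.5, 2.4]
  PRIVATE_COUNTER:
    PRIVATE: [2.0, 4.0, 7.0]
  VITALS:
    PUBLIC_OBS: [1.0, 2.0, 3.0]
    PUBLIC_GYN: [1.0, 2.0, 4.0]
    PRIVATE: [1.0, 1.0, 1.0]
  LAB:
    PUBLIC_OBS: [3.0, 4.0, 6.0]
    PRIVATE: [2.0, 3.0, 4.0]
  CONSULT:
    PUBLIC_OBS: [10.0, 13.0, 20.0]
    PUBLIC_GYN: [7.0, 10.0, 17.0]
    PRIVATE: [13.0, 17.0, 21.0]
  NURSES:
    PUBLIC_OBS: [1.0, 2.0, 4.0]
    PUBLIC_GYN: [1.0, 2.0, 4.0]
  DISCUSSION:
    default: [3.0, 5.0, 8.0]   # doctor-specialist case discussion; assumption

resources:
  qms_servers: 2
  revenue_servers: 4
  og_counter_servers: 1
  private_counter_servers: 1
  vitals_stations: 2
  lab_servers: 2
  nurses_stations: 2
  consult_rooms: 10
  doctors: 7
  specialists: 3            # of which private_specialists also serve privately
  private_specialists: 2
  # specialists handle case discussions and the afternoon private session;
  # routine public consultations are carried by the doctor pool
  specialists_see_public: false

timing:
  counters_open: "07:00"
  counters_close: "17:00"
  transfer_minutes: 2.0            # calibrated walking time between stations
  earliest_private_session: "12:30"
  specialist_lunch_minutes: 60

downtime:
  episodes_per_day: 18.97   # calibrated Poisson mean; base case only
  duration_min: 15.0
  duration_max: 60.0
  window: ["09:00", "12:00"]

arrival_shape:
  # block ("random") per-slot weights; re-gridded if the slot count differs
  public: [0.04, 0.06, 0.15, 0.15, 0.15, 0.15, 0.09, 0.08, 0.06, 0.04, 0.03]
  private: [0.50, 0.30, 0.15, 0.05]
  general: [0.04, 0.06, 0.15, 0.15, 0.15, 0.15, 0.09, 0.08, 0.06, 0.04, 0.03]
  general_slot_cap: 152

calibration:
  calibrated: true
  targets:
    obs_registration_tt: 45.0
    obs_clinic_tt: 99.0
    private_clinic_tt: 66.0
  free_parameters: [qms_median, revenue_median, og_counter_median, transfer_minutes, downtime_rate]
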