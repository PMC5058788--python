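# Calibration file: cost cells NOT printed in the source reports.
#
# status: printed  — taken directly from a published figure
#         derived  — arithmetically implied by published figures
#         assumed  — modelling assumption; edit freely, results marked as such
#
# Unit drug prices are derived so that dosing arithmetic reproduces the
# published per-administration costs (cetuximab regular $3,027.55 at
# 250 mg/m2 x 1.60 m2 = 400 mg; loading $4,844.08 at 400 mg/m2 = 640 mg;
# bevacizumab $2,608.99 at 5 mg/kg x 58 kg = 290 mg).
#
# AE unit costs: hematologic and rash are solved so that
# sum(incidence x unit cost) over each arm's grade-3/4 profile equals the
# published monthly AE costs ($105.94 cetuximab arm, $86.90 bevacizumab arm)
# given the assumed unit costs of the remaining events.

items:
  - name: cetuximab_unit_price_usd_per_mg
    value: 7.568875
    status: derived
    provenance: "published regular administration cost $3,027.55 / 400 mg dose"
  - name: bevacizumab_unit_price_usd_per_mg
    value: 8.9965172413793103
    status: derived
    provenance: "published administration cost $2,608.99 / 290 mg dose"
  - name: pooled_backbone_cost_per_admin
    value: 1223.73
    status: assumed
    provenance: "mean of published FOLFOX ($1,275.69) and FOLFIRI ($1,171.77) per-administration costs"
  - name: admin_monitoring_cost_per_cycle
    value: 350.0
    status: assumed
    provenance: "monthly administration (hospitalization, venous access) + lab/imaging monitoring; unpublished"
  - name: progression_cost_per_month
    value: 7200.0
    status: assumed
    provenance: "weighted subsequent-therapy cost per month after progression (88% treated mix); unpublished"
  - name: pd_visits_per_month
    value: 2.1741071428571427
    status: assumed
    provenance: "post-progression clinic visits at a 14-day cadence: (365.25/12)/14 per month"
  - name: ae_unit_cost_hematologic
    value: 138.72180451127818
    status: derived
    provenance: "solved from bevacizumab-arm monthly AE cost $86.90 given assumed costs of other events"
  - name: ae_unit_cost_neuropathy
    value: 150.0
    status: assumed
    provenance: "per-episode management cost of grade-3 neuropathy; unpublished"
  - name: ae_unit_cost_rash
    value: 363.28893662717507
    status: derived
    provenance: "solved from cetuximab-arm monthly AE cost $105.94 given hematologic and assumed costs"
  - name: ae_unit_cost_diarrhea
    value: 200.0
    status: assumed
    provenance: "per-episode management cost of grade-3 diarrhea; unpublished"
  - name: ae_unit_cost_hypertension
    value: 100.0
    status: assumed
    provenance: "per-episode management cost of grade-3 hypertension; unpublished"
  - name: ae_unit_cost_gastrointestinal
    value: 300.0
    status: assumed
    provenance: "per-episode management cost of grade-3/4 gastrointestinal events; unpublished"
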