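# Default population migration-route table (APPROXIMATE / SYNTHETIC STAND-IN).
#
# Waypoints follow the published out-of-Africa pathway narrative: origin at
# Addis Ababa; all non-African destinations via Cairo; Europe via Istanbul
# (or a northern detour via Chelyabinsk); Asia via Tehran/Delhi; the Americas
# via a Bering Strait crossing plus immigrant admixture components; Oceania
# via the south-Asian pathway plus UK immigration; a Pacific waypoint at
# Tahiti for Hawaii; Dakar (Senegal) as the West-African departure point for
# the ancestors of enslaved Black Africans.
#
# Coordinates, component weights, and driving-distance estimates are this
# package's own reconstruction, NOT the original supplementary table: use
# them as a demonstration default and supply a measured table for real work.
# driving_km values are coarse road-distance estimates (~1.2x great circle)
# and are omitted for ocean-crossing components (great circle then bounds
# both sides).

waypoints:
  AddisAbaba: [9.03, 38.74]
  Nairobi: [-1.29, 36.82]
  Cairo: [30.04, 31.24]
  Istanbul: [41.01, 28.98]
  Paris: [48.86, 2.35]
  London: [51.51, -0.13]
  Madrid: [40.42, -3.70]
  Chelyabinsk: [55.16, 61.40]
  Tehran: [35.69, 51.39]
  Delhi: [28.61, 77.21]
  Kolkata: [22.57, 88.36]
  Bangkok: [13.76, 100.50]
  Beijing: [39.90, 116.41]
  Tokyo: [35.68, 139.69]
  Yakutsk: [62.03, 129.68]
  BeringStrait: [65.50, -168.00]
  Anchorage: [61.22, -149.90]
  Seattle: [47.61, -122.33]
  MexicoCity: [19.43, -99.13]
  Bogota: [4.71, -74.07]
  Lima: [-12.05, -77.04]
  Dakar: [14.72, -17.47]
  Johannesburg: [-26.20, 28.05]
  Sydney: [-33.87, 151.21]
  Jakarta: [-6.21, 106.85]
  Tahiti: [-17.65, -149.43]
  Honolulu: [21.31, -157.86]
  NewYork: [40.71, -74.01]

routes:
  AFE:  # East Africa (regional dispersal around the origin)
    components:
      - {path: [AddisAbaba, Nairobi], weight: 1.0, driving_km: 1400}
  NAF:  # North Africa
    components:
      - {path: [AddisAbaba, Cairo], weight: 1.0, driving_km: 3000}
  AFS:  # Southern Africa
    components:
      - {path: [AddisAbaba, Johannesburg], weight: 1.0, driving_km: 4900}
  MDE:  # Middle East
    components:
      - {path: [AddisAbaba, Cairo, Tehran], weight: 1.0, driving_km: 5300}
  EUR:  # Europe (central/south)
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris], weight: 1.0, driving_km: 7150}
  AFM:  # African ancestry in the Americas: distance to the West-African departure point
    components:
      - {path: [AddisAbaba, Dakar], weight: 1.0, driving_km: 7400}
  PCC:  # United Kingdom cohort (larger of the two UK datasets)
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 1.0, driving_km: 7600}
  TWC:  # United Kingdom cohort (redundant with PCC; dropped by default)
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 1.0, driving_km: 7600}
  EUN:  # Northern/eastern Europe via the Caspian detour
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Chelyabinsk], weight: 1.0, driving_km: 8100}
  EUW:  # Western Europe / Iberia
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, Madrid], weight: 1.0, driving_km: 8400}
  SAS:  # South Asia
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Delhi], weight: 1.0, driving_km: 8400}
  EUA:  # European ancestry in America (distance to pre-immigration origin)
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, Madrid], weight: 0.7, driving_km: 8400}
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 0.3, driving_km: 7600}
  EAS:  # East Asia (southern Himalayan pathway)
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing], weight: 1.0, driving_km: 15800}
  JPT:  # Japan
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing, Tokyo], weight: 1.0, driving_km: 18400}
  AMN:  # North America, admixture-weighted
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 0.60, driving_km: 7600}
      - {path: [AddisAbaba, Dakar], weight: 0.25, driving_km: 7400}
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing], weight: 0.10, driving_km: 15800}
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing, Yakutsk, BeringStrait, Anchorage, Seattle], weight: 0.05, driving_km: 26500}
  AMS:  # South America, admixture-weighted
    components:
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, Madrid], weight: 0.50, driving_km: 8400}
      - {path: [AddisAbaba, Dakar], weight: 0.20, driving_km: 7400}
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing, Yakutsk, BeringStrait, Anchorage, Seattle, MexicoCity, Bogota, Lima], weight: 0.30, driving_km: 37100}
  OCE:  # Oceania: south-Asian pathway natives plus UK immigration
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Jakarta, Sydney], weight: 0.25}
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 0.75, driving_km: 7600}
  HAW:  # Hawaii: Pacific waypoint at Tahiti plus Asian/UK admixture
    components:
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Jakarta, Tahiti, Honolulu], weight: 0.50}
      - {path: [AddisAbaba, Cairo, Tehran, Delhi, Kolkata, Bangkok, Beijing], weight: 0.30, driving_km: 15800}
      - {path: [AddisAbaba, Cairo, Istanbul, Paris, London], weight: 0.20, driving_km: 7600}
  GLO:  # global pool; not rankable
    components:
      - {path: [AddisAbaba], weight: 1.0}
  OTH:  # unspecified; not rankable
    components:
      - {path: [AddisAbaba], weight: 1.0}

exclusions: [GLO, OTH]
redundancies: [TWC]
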