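# Built-in air-quality standards (thresholds in ug/m3; above is a violation).
doe_annual_pm25:
  label: Iran DOE annual PM2.5 (2014)
  pollutant: pm25
  threshold: 10
  averaging: annual
doe_24h_pm25:
  label: Iran DOE 24-h PM2.5
  pollutant: pm25
  threshold: 35
  averaging: 24-h
epa_24h_pm25:
  label: US EPA 24-h PM2.5 (2012)
  pollutant: pm25
  threshold: 35
  averaging: 24-h
doe_annual_pm10:
  label: Iran DOE annual PM10 (2014)
  pollutant: pm10
  threshold: 20
  averaging: annual
doe_24h_pm10:
  label: Iran DOE 24-h PM10
  pollutant: pm10
  threshold: 154
  averaging: 24-h
epa_24h_pm10:
  label: US EPA 24-h PM10
  pollutant: pm10
  threshold: 150
  averaging: 24-h
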