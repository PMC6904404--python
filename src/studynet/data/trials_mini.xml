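<?xml version="1.0" encoding="UTF-8"?>
<clinical_studies>
  <clinical_study>
    <id_info>
      <nct_id>NCT01234567</nct_id>
    </id_info>
    <brief_title>Multicentre haemophilia replacement-therapy study</brief_title>
    <condition>Hemophilia A</condition>
    <overall_status>Recruiting</overall_status>
    <start_date>May 1, 2016</start_date>
    <completion_date>December 31, 2019</completion_date>
    <location>
      <facility>
        <name>University of Leeds</name>
        <address>
          <city>Leeds</city>
          <zip>LS184AB</zip>
          <country>United Kingdom</country>
        </address>
      </facility>
    </location>
    <location>
      <facility>
        <name>Berlin University Hospital</name>
        <address>
          <city>Berlin</city>
          <zip>10117</zip>
          <country>Germany</country>
        </address>
      </facility>
    </location>
    <location>
      <facility>
        <name>Hospital Central de Madrid</name>
        <address>
          <city>Madrid</city>
          <zip>28001</zip>
          <country>Spain</country>
        </address>
      </facility>
    </location>
  </clinical_study>
  <clinical_study>
    <id_info>
      <nct_id>NCT07654321</nct_id>
    </id_info>
    <brief_title>Secondary prevention after myocardial infarction</brief_title>
    <condition>Myocardial Infarction</condition>
    <overall_status>Completed</overall_status>
    <start_date>March 1, 2015</start_date>
    <completion_date>June 30, 2018</completion_date>
    <location>
      <facility>
        <name>Münster University Hospital</name>
        <address>
          <city>Münster</city>
          <zip>48149</zip>
          <country>Germany</country>
        </address>
      </facility>
    </location>
  </clinical_study>
</clinical_studies>
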