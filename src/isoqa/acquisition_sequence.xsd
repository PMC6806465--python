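<?xml version="1.0" encoding="UTF-8"?>
<!-- Minimal acquisition-sequence dialect written/read by isoqa.plan.
     Not a treatment-machine format: inspectable automation artifact only. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:simpleType name="angleDeg">
    <xs:restriction base="xs:double">
      <xs:minInclusive value="0"/>
      <xs:maxExclusive value="360"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:simpleType name="positiveMm">
    <xs:restriction base="xs:double">
      <xs:minExclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:simpleType name="nonNegativeMm">
    <xs:restriction base="xs:double">
      <xs:minInclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:simpleType name="imagingMode">
    <xs:restriction base="xs:string">
      <xs:enumeration value="MV"/>
      <xs:enumeration value="kV"/>
      <xs:enumeration value="MV+kV"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:element name="sequence">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata" type="xs:string" minOccurs="0"/>
        <xs:element name="controlPoint" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="gantry" type="angleDeg" use="required"/>
            <xs:attribute name="collimator" type="angleDeg" use="required"/>
            <xs:attribute name="couch" type="angleDeg" use="required"/>
            <xs:attribute name="imagingMode" type="imagingMode" use="required"/>
            <xs:attribute name="fieldWidth" type="positiveMm" use="required"/>
            <xs:attribute name="fieldHeight" type="positiveMm" use="required"/>
            <xs:attribute name="penumbraSigma" type="nonNegativeMm" use="required"/>
            <xs:attribute name="beamQuality" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="schemaVersion" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
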